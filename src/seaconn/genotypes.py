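"""Microsatellite genotype tables and clonal population-genetic statistics.

The central data structure is :class:`GenotypeTable`, a ramets x loci table
of diploid integer allele calls (fragment lengths) with site labels and
optional site coordinates.  On top of it this module provides

* Genepop / GenAlEx-style CSV readers and writers,
* discrimination of clonal replicates (multilocus genotypes, MLGs) with the
  inbreeding-corrected probability of an MLG recurring through independent
  sexual events (p_sex),
* genotypic richness R = (MLG-1)/(N-1),
* allelic richness rarefied to a common number of genotypes (closed form
  plus Monte-Carlo SD),
* heterozygosity-based diversity summaries with a permutation test for the
  inbreeding coefficient F,
* the shared-allele distance Dps = 1 - ps between sites,
* the probability of identity (PI and PI_sibs), and
* a drift-based power simulation for detecting population differentiation
  at target F_ST values.

All statistics that assume one entry per genetic individual expect a
clone-reduced table (see :func:`identify_clones` / :func:`reduce_to_genets`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb

__all__ = [
    "GenotypeTable",
    "CloneAssignment",
    "PopulationSummary",
    "DistanceMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "site_allele_frequencies",
    "genotype_probability",
    "psex",
    "identify_clones",
    "reduce_to_genets",
    "genotypic_richness",
    "allelic_richness_std",
    "diversity_summary",
    "shared_allele_distance",
    "probability_of_identity",
    "power_simulation",
]

MISSING = 0


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Ramets x loci diploid allele calls with site labels.

    Parameters
    ----------
    ramet_ids
        One label per sampled ramet (shoot).
    sites
        Site label per ramet, aligned with ``ramet_ids``.
    alleles
        Integer array of shape ``(n_ramets, n_loci, 2)``.  Allele codes are
        positive integers (fragment lengths); ``missing_code`` marks missing
        calls.
    locus_names
        One label per locus.
    coords
        Optional mapping ``site -> (lon, lat)`` in degrees.
    """

    ramet_ids: list[str]
    sites: list[str]
    alleles: np.ndarray
    locus_names: list[str]
    coords: dict[str, tuple[float, float]] | None = None
    missing_code: int = MISSING

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 2 or self.alleles.shape[1] % 2:
            if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
                raise ValueError("alleles must have shape (n_ramets, n_loci, 2)")
        if self.alleles.ndim == 2:  # accept flat (n, 2L) layout
            self.alleles = self.alleles.reshape(len(self.ramet_ids), -1, 2)
        if len(self.ramet_ids) != self.alleles.shape[0]:
            raise ValueError("ramet_ids length does not match allele rows")
        if len(self.sites) != len(self.ramet_ids):
            raise ValueError("sites length does not match ramet_ids")
        if self.alleles.shape[1] != len(self.locus_names):
            raise ValueError("locus_names length does not match allele columns")
        if self.n_loci < 1:
            raise ValueError("at least one locus required")
        if any(not s for s in self.sites):
            raise ValueError("site labels must be non-empty")
        bad = (self.alleles < 0) | (
            (self.alleles == 0) & (self.missing_code != 0)
        )
        if bad.any():
            raise ValueError("allele codes must be positive or the missing sentinel")

    @property
    def n_ramets(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def site_order(self) -> list[str]:
        """Unique site labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)

    def site_indices(self, site: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.sites, dtype=object) == site)

    def by_site(self) -> Iterator[tuple[str, np.ndarray]]:
        for s in self.site_order:
            yield s, self.site_indices(s)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=int)
        sites = [self.sites[i] for i in idx]
        coords = None
        if self.coords is not None:
            coords = {s: self.coords[s] for s in sites if s in self.coords}
        return GenotypeTable(
            ramet_ids=[self.ramet_ids[i] for i in idx],
            sites=sites,
            alleles=self.alleles[idx],
            locus_names=list(self.locus_names),
            coords=coords,
            missing_code=self.missing_code,
        )

    def mlg_keys(self) -> list[tuple]:
        """Canonical multilocus-genotype key per ramet (allele order within a
        locus pair is irrelevant)."""
        ordered = np.sort(self.alleles, axis=2)
        return [tuple(map(int, row.ravel())) for row in ordered]

    def __eq__(self, other: object) -> bool:  # value equality for round trips
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ramet_ids == other.ramet_ids
            and self.sites == other.sites
            and self.locus_names == other.locus_names
            and self.missing_code == other.missing_code
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class CloneAssignment:
    """Clone (genet) membership for every ramet of a table.

    ``psex_values`` holds, for every MLG observed more than once within a
    site, the probability that its recurrences arose through independent
    sexual reproduction; duplicates with ``psex < alpha`` are confidently
    clonal.  All identical MLGs within a site share a ``genet_id`` and
    exactly one ramet per genet carries ``representative=True``.
    """

    ramet_ids: list[str]
    genet_ids: list[str]
    representative: np.ndarray  # bool per ramet
    psex_values: dict[str, float]  # genet_id -> p_sex (duplicated MLGs only)
    alpha: float
    sites: list[str] = field(default_factory=list)

    @property
    def n_genets(self) -> int:
        return len(set(self.genet_ids))

    def genets_per_site(self) -> dict[str, int]:
        out: dict[str, set] = {}
        for s, g in zip(self.sites, self.genet_ids):
            out.setdefault(s, set()).add(g)
        return {s: len(v) for s, v in out.items()}

    def sexual_candidates(self) -> list[str]:
        """Duplicated MLGs whose recurrence is *not* excluded as sexual
        (p_sex >= alpha)."""
        return [g for g, p in self.psex_values.items() if p >= self.alpha]


@dataclass
class PopulationSummary:
    """Per-site diversity summary (one row of a Table-1-style report)."""

    site: str
    N: int
    MLG: int
    R: float | None
    A_g: float | None = None
    A_g_sd: float | None = None
    H_O: float = np.nan
    H_O_se: float = np.nan
    H_E: float = np.nan
    H_E_se: float = np.nan
    F: float = np.nan
    F_se: float = np.nan
    F_pvalue: float = np.nan


@dataclass
class DistanceMatrix:
    """Labelled square matrix of pairwise distances."""

    labels: list[str]
    values: np.ndarray
    metric: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="site")

    @classmethod
    def from_csv(cls, path: str | Path, metric: str = "other") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(), metric=metric)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "genepop") -> GenotypeTable:
    """Read a genotype file in ``genepop`` or ``genalex_csv`` dialect.

    Genepop: title line, one locus name per line (or a single comma-separated
    line), then ``Pop`` blocks of ``label , a1a1 a2a2 ...`` rows with 2- or
    3-digit allele codes.  A label of the form ``site:ramet`` is split; a
    plain label is used as both site and ramet id.

    GenAlEx CSV: header ``ramet,site`` followed by two columns per locus
    (named ``LOC`` and ``LOC.1`` or ``LOC_2``), one row per ramet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "genalex_csv":
        return _read_genalex(path)
    raise GenotypeParseError(f"unknown format {format!r}")


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError("genepop file too short", line=len(lines))
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if not locus_names:
        raise GenotypeParseError("no locus names before first Pop", line=i)
    ramet_ids: list[str] = []
    sites: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    current_site: str | None = None
    while i < len(lines):
        line = lines[i]
        if line.strip().lower() == "pop":
            pop_idx += 1
            current_site = None
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise GenotypeParseError("expected 'label , genotypes'", line=i + 1)
        label, geno = line.split(",", 1)
        label = label.strip()
        if ":" in label:
            site, ramet = label.split(":", 1)
        else:
            site, ramet = (label or f"pop{pop_idx}"), label
        if current_site is None:
            current_site = site
        fields = geno.split()
        if len(fields) != len(locus_names):
            raise GenotypeParseError(
                f"expected {len(locus_names)} genotype fields, found {len(fields)}",
                line=i + 1,
            )
        row: list[int] = []
        for f in fields:
            if not f.isdigit() or len(f) % 2 or len(f) not in (4, 6):
                raise GenotypeParseError(f"bad genotype field {f!r}", line=i + 1)
            w = len(f) // 2
            row.extend((int(f[:w]), int(f[w:])))
        ramet_ids.append(ramet)
        sites.append(current_site if site == ramet else site)
        rows.append(row)
        i += 1
    if not rows:
        raise GenotypeParseError("no individuals found", line=i)
    return GenotypeTable(
        ramet_ids=ramet_ids,
        sites=sites,
        alleles=np.asarray(rows, dtype=np.int64),
        locus_names=locus_names,
    )


def _read_genalex(path: Path) -> GenotypeTable:
    df = pd.read_csv(path)
    if df.shape[1] < 4 or (df.shape[1] - 2) % 2:
        raise GenotypeParseError(
            f"expected 'ramet,site' plus two columns per locus, found {df.shape[1]} columns",
            line=1,
        )
    locus_cols = list(df.columns[2:])
    locus_names = []
    for j in range(0, len(locus_cols), 2):
        name = str(locus_cols[j]).split(".")[0]
        locus_names.append(name.removesuffix("_1"))
    try:
        alleles = df.iloc[:, 2:].to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise GenotypeParseError(f"non-integer allele call: {exc}", line=2) from exc
    coords = None
    return GenotypeTable(
        ramet_ids=[str(r) for r in df.iloc[:, 0]],
        sites=[str(s) for s in df.iloc[:, 1]],
        alleles=alleles.reshape(len(df), -1, 2),
        locus_names=locus_names,
        coords=coords,
    )


def write_genotypes(
    table: GenotypeTable, path: str | Path, format: str = "genepop", digits: int = 3
) -> None:
    """Write a table in ``genepop`` (``digits`` per allele) or ``genalex_csv``."""
    path = Path(path)
    if format == "genalex_csv":
        cols: dict[str, list] = {"ramet": table.ramet_ids, "site": table.sites}
        df = pd.DataFrame(cols)
        flat = table.alleles.reshape(table.n_ramets, -1)
        for j, name in enumerate(table.locus_names):
            df[name] = flat[:, 2 * j]
            df[f"{name}.1"] = flat[:, 2 * j + 1]
        df.to_csv(path, index=False)
        return
    if format != "genepop":
        raise ValueError(f"unknown format {format!r}")
    if digits not in (2, 3):
        raise ValueError("genepop allele width must be 2 or 3 digits")
    if table.alleles.max() >= 10**digits:
        raise ValueError(f"allele codes do not fit in {digits} digits")
    out = ["genotype table"]
    out.extend(table.locus_names)
    for s, idx in table.by_site():
        out.append("Pop")
        for i in idx:
            geno = " ".join(
                f"{table.alleles[i, j, 0]:0{digits}d}{table.alleles[i, j, 1]:0{digits}d}"
                for j in range(table.n_loci)
            )
            out.append(f"{s}:{table.ramet_ids[i]} ,  {geno}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def site_allele_frequencies(
    table: GenotypeTable, site: str | None = None, idx: np.ndarray | None = None
) -> list[dict[int, float]]:
    """Per-locus allele frequency dictionaries (missing calls dropped
    pairwise per locus)."""
    if idx is None:
        idx = np.arange(table.n_ramets) if site is None else table.site_indices(site)
    freqs: list[dict[int, float]] = []
    for j in range(table.n_loci):
        calls = table.alleles[idx, j, :].ravel()
        calls = calls[calls != table.missing_code]
        if calls.size == 0:
            freqs.append({})
            continue
        vals, counts = np.unique(calls, return_counts=True)
        total = counts.sum()
        freqs.append({int(v): c / total for v, c in zip(vals, counts)})
    return freqs


# ---------------------------------------------------------------------------
# clone discrimination
# ---------------------------------------------------------------------------


def genotype_probability(
    genotype: np.ndarray, freqs: Sequence[Mapping[int, float]], fis: float, missing_code: int = MISSING
) -> float:
    """Probability of a multilocus genotype under random mating with an
    inbreeding correction.

    Per locus: homozygote ``p^2 + p(1-p)F``; heterozygote ``2 p q (1-F)``.
    Loci with a missing call contribute a factor of 1.  F is clipped to
    [0, 1] so probabilities stay valid at loci with rare alleles.
    """
    f = float(np.clip(fis, 0.0, 1.0))
    p_gen = 1.0
    for j, locus_freqs in enumerate(freqs):
        a, b = int(genotype[j, 0]), int(genotype[j, 1])
        if a == missing_code or b == missing_code:
            continue
        pa = locus_freqs.get(a, 0.0)
        pb = locus_freqs.get(b, 0.0)
        if a == b:
            p_gen *= pa * pa + pa * (1.0 - pa) * f
        else:
            p_gen *= 2.0 * pa * pb * (1.0 - f)
    return p_gen


def psex(p_gen: float, n_observed: int, n_samples: int) -> float:
    """Probability of observing an MLG at least ``n_observed`` times among
    ``n_samples`` independent sexual events (binomial tail)."""
    if not 0.0 <= p_gen <= 1.0:
        raise ValueError("p_gen must be a probability")
    if n_observed < 1 or n_samples < n_observed:
        raise ValueError("need 1 <= n_observed <= n_samples")
    return float(sps.binom.sf(n_observed - 1, n_samples, p_gen))


def _site_fis(table: GenotypeTable, idx: np.ndarray) -> float:
    """Multilocus F_IS = 1 - mean(H_O)/mean(H_E) over polymorphic loci."""
    ho, he = [], []
    for j in range(table.n_loci):
        pairs = table.alleles[idx, j, :]
        ok = (pairs != table.missing_code).all(axis=1)
        pairs = pairs[ok]
        if len(pairs) == 0:
            continue
        calls = pairs.ravel()
        _, counts = np.unique(calls, return_counts=True)
        p = counts / counts.sum()
        he_j = 1.0 - float(np.sum(p**2))
        if he_j <= 0:
            continue
        ho.append(float(np.mean(pairs[:, 0] != pairs[:, 1])))
        he.append(he_j)
    if not he or np.mean(he) == 0:
        return 0.0
    return 1.0 - float(np.mean(ho)) / float(np.mean(he))


def identify_clones(table: GenotypeTable, alpha: float = 0.05) -> CloneAssignment:
    """Group ramets into genets by identical multilocus genotypes within a
    site and score duplicated MLGs with p_sex.

    Allele frequencies and F_IS for the p_sex computation are estimated from
    the distinct MLGs of each site (single pass, no re-iteration).  The
    representative of each genet is the first ramet in file order.  Sites
    with a single ramet carry no test.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    keys = table.mlg_keys()
    genet_ids = [""] * table.n_ramets
    representative = np.zeros(table.n_ramets, dtype=bool)
    psex_values: dict[str, float] = {}
    for s, idx in table.by_site():
        groups: dict[tuple, list[int]] = {}
        for i in idx:
            groups.setdefault(keys[i], []).append(int(i))
        # distinct MLGs define the genets used for frequencies and F_IS
        rep_idx = np.asarray([members[0] for members in groups.values()])
        freqs = site_allele_frequencies(table, idx=rep_idx)
        fis = _site_fis(table, rep_idx)
        n_site = len(idx)
        for g, (key, members) in enumerate(groups.items()):
            gid = f"{s}:g{g}"
            for i in members:
                genet_ids[i] = gid
            representative[members[0]] = True
            if len(members) > 1 and n_site > 1:
                p_gen = genotype_probability(
                    table.alleles[members[0]], freqs, fis, table.missing_code
                )
                psex_values[gid] = psex(p_gen, len(members), n_site)
    return CloneAssignment(
        ramet_ids=list(table.ramet_ids),
        genet_ids=genet_ids,
        representative=representative,
        psex_values=psex_values,
        alpha=alpha,
        sites=list(table.sites),
    )


def reduce_to_genets(
    table: GenotypeTable, assignment: CloneAssignment | None = None, alpha: float = 0.05
) -> GenotypeTable:
    """Return the clone-reduced table (one representative ramet per genet)."""
    if assignment is None:
        assignment = identify_clones(table, alpha=alpha)
    return table.subset(np.flatnonzero(assignment.representative))


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------


def genotypic_richness(N: int, MLG: int) -> float:
    """Genotypic (clonal) richness R = (MLG - 1) / (N - 1)."""
    if N < 2:
        raise ValueError("genotypic richness needs N >= 2 ramets")
    if not 1 <= MLG <= N:
        raise ValueError("need 1 <= MLG <= N")
    return (MLG - 1) / (N - 1)


def allelic_richness_std(
    table: GenotypeTable,
    g: int = 21,
    reps: int = 1000,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Allelic richness standardized to ``g`` genotypes per site.

    Expects a clone-reduced table.  The point estimate is the closed-form
    rarefaction: for allele *a* carried by ``G_a`` of the site's ``G``
    genets, the probability that a random subset of ``g`` genets contains
    *a* is ``1 - C(G - G_a, g) / C(G, g)``; A_g is the mean over loci of the
    per-locus sums.  The SD comes from ``reps`` Monte-Carlo subsets.  Sites
    with fewer than ``g`` genets map to ``(nan, nan)``.
    """
    if g < 2:
        raise ValueError("standardized sample size g must be >= 2")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[float, float]] = {}
    for s, idx in table.by_site():
        G = len(idx)
        if G < g:
            out[s] = (float("nan"), float("nan"))
            continue
        per_locus = []
        for j in range(table.n_loci):
            pairs = table.alleles[idx, j, :]
            ok = (pairs != table.missing_code).all(axis=1)
            pairs = pairs[ok]
            Gj = len(pairs)
            if Gj < g:
                continue
            alleles = np.unique(pairs)
            total = 0.0
            for a in alleles:
                G_a = int(np.sum((pairs == a).any(axis=1)))
                total += 1.0 - comb(Gj - G_a, g) / comb(Gj, g)
            per_locus.append(total)
        a_g = float(np.mean(per_locus)) if per_locus else float("nan")
        # Monte-Carlo SD over random genotype subsets
        draws = np.empty(reps)
        for r in range(reps):
            sub = rng.choice(idx, size=g, replace=False)
            counts = []
            for j in range(table.n_loci):
                pairs = table.alleles[sub, j, :]
                ok = (pairs != table.missing_code).all(axis=1)
                if not ok.any():
                    continue
                counts.append(len(np.unique(pairs[ok])))
            draws[r] = np.mean(counts) if counts else np.nan
        out[s] = (a_g, float(np.nanstd(draws, ddof=1)))
    return out


def _per_locus_het(
    table: GenotypeTable, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected heterozygosity per locus for one site."""
    ho = np.full(table.n_loci, np.nan)
    he = np.full(table.n_loci, np.nan)
    for j in range(table.n_loci):
        pairs = table.alleles[idx, j, :]
        ok = (pairs != table.missing_code).all(axis=1)
        pairs = pairs[ok]
        if len(pairs) == 0:
            continue
        ho[j] = float(np.mean(pairs[:, 0] != pairs[:, 1]))
        _, counts = np.unique(pairs.ravel(), return_counts=True)
        p = counts / counts.sum()
        he[j] = 1.0 - float(np.sum(p**2))
    return ho, he


def diversity_summary(
    table: GenotypeTable,
    permutations: int = 999,
    seed: int | None = None,
    ramet_counts: Mapping[str, int] | None = None,
    unbiased: bool = False,
) -> list[PopulationSummary]:
    """Per-site heterozygosities and inbreeding coefficient.

    ``table`` must be clone-reduced (one row per genet).  ``ramet_counts``
    optionally supplies the pre-reduction N per site so that R can be
    reported; otherwise N = MLG and R is left unset.

    H_O is the observed heterozygote fraction and H_E = 1 - sum(p^2), both
    averaged over loci with SE across loci.  F = (H_E - H_O) / H_E per
    polymorphic locus, averaged; its significance comes from a two-tailed
    permutation test that shuffles allele copies among genets within each
    locus (monomorphic loci are excluded from F).  ``unbiased`` applies the
    2n/(2n-1) small-sample correction to H_E (off by default, matching the
    uncorrected convention of the reported tables).
    """
    rng = np.random.default_rng(seed)
    results: list[PopulationSummary] = []
    for s, idx in table.by_site():
        mlg = len(idx)
        n = int(ramet_counts[s]) if ramet_counts is not None else mlg
        r = genotypic_richness(n, mlg) if n >= 2 and ramet_counts is not None else None
        ho, he = _per_locus_het(table, idx)
        if unbiased and mlg > 0:
            he = he * (2 * mlg) / (2 * mlg - 1)
        valid = ~np.isnan(ho)
        poly = valid & (he > 0)
        f_obs, f_se = np.nan, np.nan
        if poly.any():
            f_loc = (he[poly] - ho[poly]) / he[poly]
            f_obs = float(np.mean(f_loc))
            f_se = float(np.std(f_loc, ddof=1) / np.sqrt(poly.sum())) if poly.sum() > 1 else np.nan
        # permutation null for F: shuffle allele copies among genets per locus
        f_p = np.nan
        if poly.any() and permutations > 0 and mlg > 1:
            poly_j = np.flatnonzero(poly)
            hits = 0
            for _ in range(permutations):
                f_perm = []
                for j in poly_j:
                    calls = table.alleles[idx, j, :].ravel()
                    calls = calls[calls != table.missing_code]
                    perm = rng.permutation(calls)
                    pairs = perm.reshape(-1, 2)
                    ho_p = float(np.mean(pairs[:, 0] != pairs[:, 1]))
                    f_perm.append((he[j] - ho_p) / he[j])
                if abs(np.mean(f_perm)) >= abs(f_obs) - 1e-12:
                    hits += 1
            f_p = (1 + hits) / (1 + permutations)
        nv = valid.sum()
        results.append(
            PopulationSummary(
                site=s,
                N=n,
                MLG=mlg,
                R=r,
                H_O=float(np.nanmean(ho)),
                H_O_se=float(np.nanstd(ho, ddof=1) / np.sqrt(nv)) if nv > 1 else np.nan,
                H_E=float(np.nanmean(he)),
                H_E_se=float(np.nanstd(he, ddof=1) / np.sqrt(nv)) if nv > 1 else np.nan,
                F=f_obs,
                F_se=f_se,
                F_pvalue=f_p,
            )
        )
    return results


def summaries_to_frame(summaries: Iterable[PopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


# ---------------------------------------------------------------------------
# shared-allele distance
# ---------------------------------------------------------------------------


def shared_allele_distance(
    table: GenotypeTable, method: str = "frequency"
) -> DistanceMatrix:
    """Pairwise Dps = 1 - ps between sites on a clone-reduced table.

    ``method='frequency'`` (default): ps per locus is the summed minimum of
    the two sites' allele frequencies, averaged over loci.
    ``method='individual'``: ps is averaged over all between-site genet
    pairs, with per-pair locus sharing min(count_a, count_b)/2.
    """
    sites = table.site_order
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    keep = [s for s in sites if len(table.site_indices(s)) > 0]
    if len(keep) < len(sites):
        warnings.warn("sites with zero genets excluded from Dps")
    n = len(keep)
    values = np.zeros((n, n))
    if method == "frequency":
        freqs = {s: site_allele_frequencies(table, s) for s in keep}
        for a in range(n):
            for b in range(a + 1, n):
                ps_loci = []
                for j in range(table.n_loci):
                    fa, fb = freqs[keep[a]][j], freqs[keep[b]][j]
                    if not fa or not fb:
                        continue
                    shared = sum(min(fa.get(al, 0.0), fb.get(al, 0.0)) for al in set(fa) | set(fb))
                    ps_loci.append(shared)
                d = 1.0 - float(np.mean(ps_loci)) if ps_loci else np.nan
                values[a, b] = values[b, a] = d
    elif method == "individual":
        for a in range(n):
            ia = table.site_indices(keep[a])
            for b in range(a + 1, n):
                ib = table.site_indices(keep[b])
                ps_pairs = []
                for i in ia:
                    for k in ib:
                        ps_loci = []
                        for j in range(table.n_loci):
                            gi = table.alleles[i, j, :]
                            gk = table.alleles[k, j, :]
                            if (gi == table.missing_code).any() or (gk == table.missing_code).any():
                                continue
                            shared = 0
                            used = list(gk)
                            for al in gi:
                                if al in used:
                                    shared += 1
                                    used.remove(al)
                            ps_loci.append(shared / 2.0)
                        if ps_loci:
                            ps_pairs.append(np.mean(ps_loci))
                d = 1.0 - float(np.mean(ps_pairs)) if ps_pairs else np.nan
                values[a, b] = values[b, a] = d
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(labels=keep, values=np.clip(values, 0.0, 1.0), metric="Dps")


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------


def probability_of_identity(table: GenotypeTable) -> pd.DataFrame:
    """Per-site probability that two independent sexual individuals share a
    multilocus genotype.

    Per locus ``PI = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2`` and
    ``PI_sibs = 0.25 + 0.5 S2 + 0.5 S2^2 - 0.25 S4`` with ``S2 = sum p^2``
    and ``S4 = sum p^4``; both multiply across loci.  Computed from genet
    allele frequencies (pass a clone-reduced table).
    """
    rows = []
    for s, _ in table.by_site():
        freqs = site_allele_frequencies(table, s)
        pi, pi_sibs = 1.0, 1.0
        for locus_freqs in freqs:
            if not locus_freqs:
                continue
            p = np.asarray(list(locus_freqs.values()))
            s2 = float(np.sum(p**2))
            s4 = float(np.sum(p**4))
            outer = np.outer(p, p)
            het_sq = float(np.sum((2 * outer) ** 2) - np.sum((2 * p**2) ** 2)) / 2.0
            pi *= s4 + het_sq
            pi_sibs *= 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        rows.append({"site": s, "PI": pi, "PI_sibs": pi_sibs})
    return pd.DataFrame(rows).set_index("site")


# ---------------------------------------------------------------------------
# power simulation
# ---------------------------------------------------------------------------


def _fst_generations(fst: float, ne: int, t_max: int) -> int:
    """Generations of drift so that expected F_ST = 1 - (1 - 1/(2Ne))^t."""
    if fst < 0 or fst >= 1:
        raise ValueError("target F_ST must be in [0, 1)")
    if fst == 0:
        return 0
    t = math.log(1.0 - fst) / math.log(1.0 - 1.0 / (2 * ne))
    t_int = max(1, round(t))
    if t_int > t_max:
        raise ValueError(f"target F_ST {fst} needs t={t_int} > t_max={t_max} generations")
    return t_int


def power_simulation(
    table: GenotypeTable,
    Ne: int = 200,
    fst_targets: Sequence[float] = (0.0, 0.001, 0.01, 0.1),
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    t_max: int = 1000,
) -> dict[float, float]:
    """Drift-based power to detect differentiation at target F_ST values.

    For each target the base (pooled) allele frequencies drift independently
    in every site for ``t`` generations with binomial sampling of ``2 Ne``
    gene copies, where ``t`` satisfies ``F_ST = 1 - (1 - 1/(2 Ne))^t``.
    Samples of the observed per-site sizes are drawn from the drifted
    frequencies, and homogeneity is tested with per-locus contingency
    chi-square summed over loci.  Returns ``{target: rejection rate}``; at
    F_ST = 0 the value is the realized type-I error.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    sites = table.site_order
    n_sites = len(sites)
    if n_sites < 2:
        raise ValueError("need at least two sites")
    sample_sizes = np.asarray([2 * len(table.site_indices(s)) for s in sites])
    pooled = site_allele_frequencies(table)  # over all genets
    loci_p = []
    for f in pooled:
        if len(f) >= 2:
            loci_p.append(np.asarray(list(f.values()), dtype=float))
    if not loci_p:
        raise ValueError("no polymorphic loci")
    out: dict[float, float] = {}
    for target in fst_targets:
        t = _fst_generations(target, Ne, t_max)
        stat = np.zeros(reps)
        dof = np.zeros(reps, dtype=int)
        for p0 in loci_p:
            k = len(p0)
            # drift all reps x sites in parallel
            p = np.broadcast_to(p0, (reps, n_sites, k)).copy()
            for _ in range(t):
                counts = rng.multinomial(2 * Ne, p)
                p = counts / (2.0 * Ne)
            obs = np.empty((reps, n_sites, k), dtype=np.int64)
            for s_i in range(n_sites):
                obs[:, s_i, :] = rng.multinomial(sample_sizes[s_i], p[:, s_i, :])
            col = obs.sum(axis=1, keepdims=True)  # (reps, 1, k)
            row = obs.sum(axis=2, keepdims=True)  # (reps, sites, 1)
            tot = col.sum(axis=2, keepdims=True)  # (reps, 1, 1)
            expected = row * col / tot
            with np.errstate(divide="ignore", invalid="ignore"):
                cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
            stat += cells.sum(axis=(1, 2))
            k_eff = (col[:, 0, :] > 0).sum(axis=1)
            dof += np.maximum(k_eff - 1, 0) * (n_sites - 1)
        pvals = sps.chi2.sf(stat, np.maximum(dof, 1))
        out[float(target)] = float(np.mean(pvals < alpha))
    return out
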