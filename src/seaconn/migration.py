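"""Directional relative migration between sites from allele frequencies.

Implements the G_ST-based directional method: for every ordered pair of
sites a hypothetical migrant pool is formed from the normalized geometric
mean of the two sites' allele frequencies; the differentiation of the source
site from that pool, converted through m = ((1/d) - 1) / 4, gives the
relative amount of migration out of that site into the other (migrants in
the pool resemble their source, so a site close to the pool exports).  The
final
matrix is normalized by its maximum, so entries live in [0, 1] with the
strongest flow equal to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from seaconn.genotypes import GenotypeTable, site_allele_frequencies

__all__ = ["DirectionalMigrationMatrix", "directional_relative_migration"]


@dataclass
class DirectionalMigrationMatrix:
    """Asymmetric site x site relative migration (rows = source,
    columns = recipient); diagonal is undefined (nan)."""

    labels: list[str]
    values: np.ndarray
    bootstrap_p: np.ndarray | None = None  # per ordered pair asymmetry p

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        with open(path, "w") as fh:
            fh.write("# relative migration: rows = source site, columns = recipient site\n")
            df.to_csv(fh, index_label="site")


def _gst(freq_a: list[dict[int, float]], freq_b: list[dict[int, float]]) -> float:
    """Nei's G_ST between two equally weighted populations, loci averaged."""
    hs, ht = [], []
    for fa, fb in zip(freq_a, freq_b):
        if not fa or not fb:
            continue
        alleles = set(fa) | set(fb)
        pa = np.asarray([fa.get(al, 0.0) for al in alleles])
        pb = np.asarray([fb.get(al, 0.0) for al in alleles])
        pbar = (pa + pb) / 2.0
        hs.append(1.0 - (np.sum(pa**2) + np.sum(pb**2)) / 2.0)
        ht.append(1.0 - np.sum(pbar**2))
    if not ht or np.mean(ht) == 0:
        return 0.0
    return float((np.mean(ht) - np.mean(hs)) / np.mean(ht))


def _geometric_pool(
    freq_a: list[dict[int, float]], freq_b: list[dict[int, float]]
) -> list[dict[int, float]]:
    """Per-allele geometric mean of two frequency sets, renormalized.
    Alleles absent from either site get zero weight."""
    pool: list[dict[int, float]] = []
    for fa, fb in zip(freq_a, freq_b):
        alleles = set(fa) | set(fb)
        gm = {al: np.sqrt(fa.get(al, 0.0) * fb.get(al, 0.0)) for al in alleles}
        total = sum(gm.values())
        if total > 0:
            pool.append({al: v / total for al, v in gm.items()})
        else:
            pool.append({})
    return pool


def _migration_values(freqs: dict[str, list[dict[int, float]]], labels: list[str]) -> np.ndarray:
    n = len(labels)
    raw = np.full((n, n), np.nan)
    undefined: list[tuple[int, int]] = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            pool = _geometric_pool(freqs[labels[a]], freqs[labels[b]])
            # the pool stands for the migrants; migrants resemble their
            # source, so flow out of a is strong when a sits close to the
            # pool (small d_a)
            d_a = _gst(freqs[labels[a]], pool)
            if d_a <= 0:
                undefined.append((a, b))
                continue
            raw[a, b] = (1.0 / d_a - 1.0) / 4.0
    finite = raw[np.isfinite(raw)]
    peak = finite.max() if finite.size else 1.0
    for a, b in undefined:
        raw[a, b] = peak
    return raw, bool(undefined)


def directional_relative_migration(
    table: GenotypeTable,
    stat: str = "gst",
    bootstraps: int = 1000,
    seed: int | None = None,
) -> DirectionalMigrationMatrix:
    """Directional relative migration from a clone-reduced genotype table.

    Entry ``[i, j]`` is the relative migration from site i into site j.
    ``bootstraps`` resamples of genets within sites give a two-sided p-value
    for the asymmetry ``m[i,j] - m[j,i]`` of each pair (the fraction of
    bootstrap replicates in which the sign of the asymmetry flips, doubled);
    pass ``bootstraps=0`` to skip.
    """
    if stat != "gst":
        raise NotImplementedError("only the G_ST variant is implemented")
    labels = table.site_order
    if len(labels) < 2:
        raise ValueError("need at least two sites")
    rng = np.random.default_rng(seed)
    freqs = {s: site_allele_frequencies(table, s) for s in labels}
    raw, had_undefined = _migration_values(freqs, labels)
    if had_undefined:
        warnings.warn("identical pools for some pairs; entries set to matrix maximum")
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        raise ValueError("no defined site pair")
    values = raw / finite.max() if finite.max() > 0 else raw
    boot_p = None
    if bootstraps > 0:
        n = len(labels)
        site_idx = {s: table.site_indices(s) for s in labels}
        diffs = np.zeros((bootstraps, n, n))
        for r in range(bootstraps):
            bfreqs = {}
            for s in labels:
                idx = site_idx[s]
                resampled = rng.choice(idx, size=len(idx), replace=True)
                bfreqs[s] = site_allele_frequencies(table, idx=resampled)
            m, _ = _migration_values(bfreqs, labels)
            diffs[r] = m - m.T
        obs = raw - raw.T
        sign_flip = np.mean(np.sign(diffs) != np.sign(obs)[None, :, :], axis=0)
        boot_p = np.minimum(2 * np.minimum(sign_flip, 1 - sign_flip) + 1.0 / bootstraps, 1.0)
        np.fill_diagonal(boot_p, np.nan)
    return DirectionalMigrationMatrix(labels=labels, values=values, bootstrap_p=boot_p)
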