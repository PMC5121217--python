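"""OTU-table analytics for the reactor-microbiome component.

Relative abundance, the 1%-in-at-least-one-sample abundance filter, Shannon
alpha diversity, Bray-Curtis dissimilarity with average-linkage (UPGMA)
clustering for heat-map ordering, principal coordinates analysis, and the
Pearson gate that flags OTUs whose relative abundance is positively
correlated with MCC productivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "OtuTable",
    "PCoAResult",
    "relative_abundance",
    "abundant_otus",
    "shannon_index",
    "shannon_per_sample",
    "critical_pearson_r",
    "correlate_otus",
    "bray_curtis",
    "bray_curtis_cluster",
    "pcoa",
]


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with sample metadata.

    ``counts`` is indexed by sample id with OTU ids as columns; entries are
    nonnegative integers.  ``metadata`` (optional) is indexed by sample id
    with columns such as ``day`` and ``productivity`` (g COD/L-d; absent,
    i.e. NaN, for inoculum/substrate samples).  ``taxonomy`` (optional) maps
    OTU id to a taxonomy string.
    """

    counts: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None
    taxonomy: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("OTU ids must be unique")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        if self.metadata is not None:
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing for samples: {list(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def remove_singletons(self) -> "OtuTable":
        """Drop OTUs whose total count across all samples is exactly 1."""
        keep = self.counts.sum(axis=0) != 1
        tax = self.taxonomy[self.counts.columns[keep]] if self.taxonomy is not None else None
        return OtuTable(self.counts.loc[:, keep], self.metadata, tax)

    def productivity(self) -> pd.Series:
        """Productivity vector over samples that carry it (drops NaN)."""
        if self.metadata is None or "productivity" not in self.metadata:
            raise ValueError("table has no productivity metadata")
        return self.metadata.loc[self.counts.index, "productivity"].dropna()


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total count: {empty}")
    return table.counts.div(totals, axis=0)


def abundant_otus(
    table: OtuTable, threshold: float = 0.01, strict: bool = False
) -> list[str]:
    """OTUs reaching the relative-abundance threshold in >= 1 sample.

    Inclusive (>=) by default; ``strict=True`` uses a strict > comparison.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rel = relative_abundance(table)
    peak = rel.max(axis=0)
    if threshold == 0.0 and not strict:
        mask = table.counts.sum(axis=0) > 0
    else:
        mask = (peak > threshold) if strict else (peak >= threshold)
    return list(peak.index[mask])


def shannon_index(proportions: Sequence[float], base: float = 2.0) -> float:
    """Shannon diversity -sum(p * log_base p), zeros excluded.

    Base 2 by default (the convention of the upstream amplicon pipelines);
    pass ``base=math.e`` for nats.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    total = p.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"proportions must sum to 1 (got {total})")
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def shannon_per_sample(table: OtuTable, base: float = 2.0) -> pd.Series:
    rel = relative_abundance(table)
    return rel.apply(lambda row: shannon_index(row.to_numpy(), base=base), axis=1)


def critical_pearson_r(n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Critical Pearson |r| at significance alpha for n paired samples.

    From the t transform of r with n-2 degrees of freedom:
    ``t / sqrt(t^2 + n - 2)`` with ``t = t_(1 - alpha/2, n-2)`` (two-sided)
    or ``t_(1 - alpha, n-2)`` (one-sided).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    t = stats.t.ppf(q, n - 2)
    return float(t / math.sqrt(t**2 + n - 2))


def correlate_otus(
    table: OtuTable,
    productivity: Optional[pd.Series] = None,
    *,
    alpha: float = 0.05,
    abundance_threshold: float = 0.01,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of OTU relative abundance with MCC productivity.

    Only OTUs passing the abundance filter are tested.  p-values are
    two-sided from the t transform; an OTU is flagged ``significant`` when
    r exceeds the two-sided critical value (positive-direction gate).
    Zero-variance abundance vectors yield ``undefined=True`` with NaN r/p
    rather than propagating NaN silently.  An optional Benjamini-Hochberg
    correction on the p-values is off by default.
    """
    if productivity is None:
        productivity = table.productivity()
    samples = productivity.index
    if len(samples) < 3:
        raise ValueError("need >= 3 samples with productivity metadata")
    rel = relative_abundance(table).loc[samples]
    otus = abundant_otus(table, threshold=abundance_threshold)
    n = len(samples)
    r_crit = critical_pearson_r(n, alpha=alpha, two_sided=True)
    rows = []
    for otu in otus:
        x = rel[otu].to_numpy()
        if np.std(x) == 0 or np.std(productivity.to_numpy()) == 0:
            rows.append(dict(otu_id=otu, r=np.nan, p=np.nan, significant=False, undefined=True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = stats.pearsonr(x, productivity.to_numpy())
        rows.append(
            dict(otu_id=otu, r=float(r), p=float(p), significant=bool(r > r_crit), undefined=False)
        )
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        ok = out["p"].notna()
        p = out.loc[ok, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        out.loc[ok, "p_adjusted"] = adj
        out.loc[ok, "significant"] = (out.loc[ok, "r"] > r_crit) & (out.loc[ok, "p_adjusted"] < alpha)
    if table.taxonomy is not None and len(out):
        out.insert(1, "taxonomy", out["otu_id"].map(table.taxonomy))
    return out


def bray_curtis(table: OtuTable, axis: str = "samples") -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix on relative abundances.

    ``axis="samples"`` compares samples; ``axis="otus"`` compares OTU
    abundance profiles across samples (the heat-map row ordering).
    """
    rel = relative_abundance(table)
    if axis == "otus":
        rel = rel.T
    elif axis != "samples":
        raise ValueError("axis must be 'samples' or 'otus'")
    d = squareform(pdist(rel.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=rel.index, columns=rel.index)


def bray_curtis_cluster(
    table: OtuTable, axis: str = "samples"
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Average-linkage (UPGMA) clustering on Bray-Curtis dissimilarities.

    Returns the distance matrix, the SciPy linkage matrix, and the
    dendrogram leaf order (ids) used to arrange heat-map rows.  Equal merge
    heights are broken deterministically by input order, so the ordering is
    reproducible for a fixed table.
    """
    dm = bray_curtis(table, axis=axis)
    z = hierarchy.linkage(squareform(dm.to_numpy(), checks=False), method="average")
    order = [dm.index[i] for i in hierarchy.leaves_list(z)]
    return dm, z, order


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` holds sample scores (axes as columns),
    ``proportion_explained`` the per-axis variance fractions, ``eigvals``
    all eigenvalues (negatives, which arise for non-Euclidean
    dissimilarities, are reported rather than hidden).
    """

    coordinates: pd.DataFrame
    proportion_explained: pd.Series
    eigvals: pd.Series

    @property
    def has_negative_eigenvalues(self) -> bool:
        scale = max(abs(self.eigvals.max()), 1e-300)
        return bool((self.eigvals / scale < -1e-8).any())


def pcoa(distance_matrix: pd.DataFrame) -> PCoAResult:
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    The matrix must be symmetric with a zero diagonal.  Variance-explained
    fractions are nonincreasing across axes.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    ids = [str(i) for i in distance_matrix.index] if isinstance(
        distance_matrix, pd.DataFrame
    ) else None
    with warnings.catch_warnings():
        # skbio warns on negative eigenvalues; we report them explicitly.
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix(d, ids=ids), method="eigh")
    return PCoAResult(
        coordinates=res.samples,
        proportion_explained=res.proportion_explained,
        eigvals=res.eigvals,
    )
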