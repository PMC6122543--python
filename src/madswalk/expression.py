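"""Relative qPCR expression: 2^-ΔΔCt quantification, replicate statistics,
group tests, and hierarchical clustering of the gene x sample matrix.

ΔCt is computed per replicate against the reference (housekeeping) gene,
ΔΔCt against the calibrator sample, and fold change as 2^-ΔΔCt with an
amplification efficiency fixed at 2. Genes with missing Ct values in a
sample are flagged rather than silently dropped; clustering excludes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def _delta_ct(ct: pd.DataFrame, gene: str, ref_gene: str, sample: str) -> np.ndarray:
    """Per-replicate ΔCt = Ct(target) - Ct(reference), paired by replicate."""
    sub = ct[ct["sample"] == sample]
    tgt = sub[sub["gene"] == gene].sort_values("replicate")["ct"].to_numpy()
    ref = sub[sub["gene"] == ref_gene].sort_values("replicate")["ct"].to_numpy()
    if len(ref) == 0:
        raise KeyError(f"no reference-gene measurements for sample {sample!r}")
    if len(tgt) != len(ref):
        raise ValueError(
            f"replicate count mismatch for gene {gene!r} in sample {sample!r}"
        )
    return tgt - ref


def ddct(ct: pd.DataFrame, ref_gene: str, calibrator: str = "leaf") -> pd.DataFrame:
    """Relative expression by the 2^-ΔΔCt method.

    ``ct`` is a long-format table (sample, gene, replicate, ct). Returns one
    row per (gene, sample) with fold change, the SD of replicate ΔCt values,
    a two-sided t-test p-value against the calibrator sample, and a flag
    ("ok", "not_detected", or "no_reference").
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    genes = [g for g in ct["gene"].unique() if g != ref_gene]
    samples = list(ct["sample"].unique())
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    if ref_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {ref_gene!r} not in table")
    rows = []
    for gene in genes:
        try:
            dct_cal = _delta_ct(ct, gene, ref_gene, calibrator)
        except KeyError:
            dct_cal = None
        for sample in samples:
            try:
                dct = _delta_ct(ct, gene, ref_gene, sample)
            except KeyError:
                rows.append((gene, sample, np.nan, np.nan, np.nan, "no_reference"))
                continue
            if np.isnan(dct).any() or dct_cal is None or np.isnan(dct_cal).any():
                rows.append((gene, sample, np.nan, np.nan, np.nan, "not_detected"))
                continue
            dd = dct.mean() - dct_cal.mean()
            fold = float(2.0 ** (-dd))
            sd = float(np.std(dct, ddof=1)) if len(dct) > 1 else 0.0
            if sample == calibrator:
                p = 1.0
            elif len(dct) >= 2 and len(dct_cal) >= 2:
                _, p = group_test(list(dct), list(dct_cal))
            else:
                p = np.nan
            rows.append((gene, sample, fold, sd, p, "ok"))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "fold", "sd", "p_value", "flag"]
    )


def group_test(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance), two-sided."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    with warnings.catch_warnings():
        # constant replicate groups trigger a scipy precision warning; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0
    return t, p


def significance_flag(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class Dendrogram:
    """Agglomerative merge history over genes."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    dropped: list[str]  # genes excluded for missing values

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Merge history as (member set A, member set B, height)."""
        n = len(self.labels)
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for k, (i, j, h, _) in enumerate(self.linkage):
            a, b = clusters[int(i)], clusters[int(j)]
            out.append((a, b, float(h)))
            clusters[n + k] = a | b
        return out

    def newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        inner = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def hcluster(
    expr: pd.DataFrame, distance: str = "1-pearson", linkage: str = "average"
) -> Dendrogram:
    """Average-linkage agglomerative clustering of genes by expression profile.

    ``expr`` is a gene x sample matrix of log2 fold changes. Rows with any
    missing value are dropped (and reported on the result). Distances are
    euclidean or 1 - Pearson correlation.
    """
    keep = expr.dropna(axis=0)
    dropped = sorted(set(expr.index) - set(keep.index))
    if len(keep) < 2:
        raise ValueError("need at least 2 complete gene rows to cluster")
    X = keep.to_numpy(dtype=float)
    if distance == "euclidean":
        d = pdist(X, metric="euclidean")
    elif distance == "1-pearson":
        if (X.std(axis=1) == 0).any():
            zero = [g for g, row in zip(keep.index, X) if row.std() == 0]
            raise ValueError(f"zero-variance rows under 1-pearson distance: {zero}")
        d = pdist(X, metric="correlation")
    else:
        raise ValueError("distance must be 'euclidean' or '1-pearson'")
    Z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(linkage=Z, labels=list(keep.index), dropped=dropped)
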