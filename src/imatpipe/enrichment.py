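"""Gene set enrichment (GSEA, phenotype permutation) and PLS-DA/VIP signatures.

GSEA ranks genes by Pearson correlation with the phenotype vector, walks a
weighted Kolmogorov-Smirnov running sum for each gene set (hit increments
proportional to |score|^p, miss decrements 1/(N - N_hits)), and assesses
significance against a phenotype-permutation null: labels are permuted and
genes re-ranked for every permutation.  NES divides the observed ES by the
mean |null ES| of matching sign, and the FDR q-value follows the
sign-matched pooled-null convention of the original GSEA method.  Two
significance rules are reported: the strict cell-line rule
(FDR <= 0.1, NES > 1.5, leading-edge signal > 50%) and the lenient
tumor-panel rule (FDR <= 0.25).

PLS-DA fits partial least squares against dummy-coded class membership; the
variable importance in projection of gene j over a components is

    VIP_j = sqrt( p * sum_a w_ja^2 SS_a / sum_a SS_a )

with w_a the unit-norm X-weights and SS_a the class variance explained by
component a; sum_j VIP_j^2 = p (the gene count) by construction.  Genes with
VIP >= 1.5 form the discriminative signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .omics_integration import ExpressionProfile

__all__ = [
    "pearson_rank",
    "enrichment_score",
    "gsea",
    "plsda_vip",
    "select_signature",
    "VipScores",
    "read_gmt",
    "write_gmt",
]

#: strict significance rule (cell-line comparison)
FDR_STRICT, NES_MIN, LEADING_EDGE_MIN = 0.1, 1.5, 0.5
#: lenient rule (tumor-stage panels)
FDR_LENIENT = 0.25

VIP_THRESHOLD = 1.5


def _stack(expr_a: ExpressionProfile, expr_b: ExpressionProfile
           ) -> Tuple[pd.DataFrame, np.ndarray]:
    genes = expr_a.genes.intersection(expr_b.genes)
    if genes.empty:
        raise ValueError("expression profiles share no genes")
    X = pd.concat(
        [expr_a.data.loc[genes], expr_b.data.loc[genes]], axis=1,
        keys=[expr_a.condition, expr_b.condition],
    )
    labels = np.r_[np.ones(expr_a.data.shape[1]),
                   np.zeros(expr_b.data.shape[1])]
    return X, labels


def _pearson_scores(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation with one or many label vectors.

    ``labels`` may be (s,) or (s, P); constant rows (or labels) score 0.
    """
    L = labels if labels.ndim == 2 else labels[:, None]
    Xc = X - X.mean(axis=1, keepdims=True)
    Lc = L - L.mean(axis=0, keepdims=True)
    num = Xc @ Lc
    xsd = np.sqrt((Xc**2).sum(axis=1))
    lsd = np.sqrt((Lc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / np.outer(xsd, lsd)
    r[~np.isfinite(r)] = 0.0
    return r if labels.ndim == 2 else r[:, 0]


def pearson_rank(
    expr_a: ExpressionProfile,
    expr_b: ExpressionProfile,
    phenotype: Optional[Sequence[float]] = None,
) -> pd.Series:
    """Genes ranked by Pearson correlation with the phenotype.

    Phenotype defaults to binary 1 (condition A samples) / 0 (condition B);
    an explicit vector (e.g. ordinal tumor stages) may be supplied.  Returns
    a Series gene -> score, sorted by score descending with ties broken by
    gene id ascending.  Constant genes score 0.
    """
    X, labels = _stack(expr_a, expr_b)
    if phenotype is not None:
        labels = np.asarray(phenotype, dtype=float)
        if labels.shape[0] != X.shape[1]:
            raise ValueError("phenotype length does not match sample count")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples to rank by correlation")
    scores = pd.Series(_pearson_scores(X.to_numpy(dtype=float), labels),
                       index=X.index, name="score")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


def _es_walk(
    scores: np.ndarray, hit: np.ndarray, weight_p: float
) -> Tuple[float, np.ndarray, int]:
    """Running-sum walk; returns (ES, running profile, extremum position)."""
    n = scores.shape[0]
    nh = int(hit.sum())
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set scores are exactly zero: flat hit steps
        hit_inc = np.where(hit, 1.0 / nh, 0.0)
    else:
        hit_inc = hit_w / total
    miss_dec = np.where(hit, 0.0, 1.0 / (n - nh))
    running = np.cumsum(hit_inc - miss_dec)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), running, pos


def enrichment_score(
    ranked: pd.Series, gene_set: Sequence[str], weight_p: float = 1.0
) -> Tuple[float, np.ndarray, List[str]]:
    """Weighted KS enrichment score of one gene set on a ranked list.

    Returns (ES, running profile, leading-edge genes).  The leading edge is
    the set's genes at or before the running-sum extremum for positive ES,
    at or after it for negative ES.
    """
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set does not intersect the ranked list")
    if len(members) == len(ranked):
        raise ValueError("gene set covers the whole ranked list")
    hit = ranked.index.isin(members)
    es, running, pos = _es_walk(ranked.to_numpy(dtype=float), hit, weight_p)
    if es >= 0:
        le_mask = hit & (np.arange(len(ranked)) <= pos)
    else:
        le_mask = hit & (np.arange(len(ranked)) >= pos)
    leading = list(ranked.index[le_mask])
    return es, running, leading


def gsea(
    expr_a: ExpressionProfile,
    expr_b: ExpressionProfile,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: Optional[int] = None,
    phenotype: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """GSEA with phenotype permutation.

    Labels are permuted ``n_perm`` times and genes re-ranked per permutation;
    ES, NES, nominal p and FDR q follow the sign-matched conventions
    described in the module docstring.  Reproducible for a fixed seed.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if expr_a.data.shape[1] < 2 or expr_b.data.shape[1] < 2:
        raise ValueError("need at least 2 samples per class to permute")
    X, labels = _stack(expr_a, expr_b)
    if phenotype is not None:
        labels = np.asarray(phenotype, dtype=float)
    Xv = X.to_numpy(dtype=float)
    genes = X.index

    ranked = pearson_rank(expr_a, expr_b, phenotype=phenotype)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(labels) for _ in range(n_perm)], axis=1)
    null_scores = _pearson_scores(Xv, perms)  # genes x n_perm
    null_order = np.argsort(-null_scores, axis=0, kind="stable")

    records = []
    null_es = np.empty((len(gene_sets), n_perm))
    names = list(gene_sets)
    for si, name in enumerate(names):
        members = set(gene_sets[name]) & set(genes)
        es, _, leading = enrichment_score(ranked, gene_sets[name], weight_p)
        hit_base = np.asarray(genes.isin(members))
        for p in range(n_perm):
            order = null_order[:, p]
            s = null_scores[order, p]
            null_es[si, p] = _es_walk(s, hit_base[order], weight_p)[0]
        n_hits = int(hit_base.sum())
        records.append(
            dict(name=name, es=es, n_genes=n_hits,
                 leading_edge_genes=",".join(leading),
                 leading_edge_signal=len(leading) / n_hits)
        )
    df = pd.DataFrame(records).set_index("name")

    # sign-matched normalization and nominal p
    nes = np.empty(len(names))
    pvals = np.empty(len(names))
    nes_null = np.zeros_like(null_es)
    for si in range(len(names)):
        row = null_es[si]
        pos, neg = row[row > 0], row[row < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null[si] = np.where(row >= 0, row / pos_mean, row / neg_mean)
        nes_null[si][~np.isfinite(nes_null[si])] = 0.0
        es = df["es"].iloc[si]
        if es >= 0:
            nes[si] = es / pos_mean if pos.size else np.nan
            pvals[si] = (row >= es).sum() / pos.size if pos.size else 1.0 / n_perm
        else:
            nes[si] = es / neg_mean if neg.size else np.nan
            pvals[si] = (row <= es).sum() / neg.size if neg.size else 1.0 / n_perm
    pvals = np.clip(pvals, 1.0 / n_perm, 1.0)

    # FDR: pooled sign-matched null NES vs observed NES
    fdr = np.empty(len(names))
    pooled = nes_null.ravel()
    pooled_pos, pooled_neg = pooled[pooled >= 0], pooled[pooled < 0]
    obs_pos, obs_neg = nes[nes >= 0], nes[nes < 0]
    for si, val in enumerate(nes):
        if np.isnan(val):
            fdr[si] = 1.0
            continue
        if val >= 0:
            num = (pooled_pos >= val).mean() if pooled_pos.size else 1.0
            den = (obs_pos >= val).mean() if obs_pos.size else 1.0
        else:
            num = (pooled_neg <= val).mean() if pooled_neg.size else 1.0
            den = (obs_neg <= val).mean() if obs_neg.size else 1.0
        fdr[si] = min(1.0, num / den) if den > 0 else 1.0

    df["nes"] = nes
    df["pval"] = pvals
    df["fdr"] = fdr
    df["significant_cellline_rule"] = (
        (df["fdr"] <= FDR_STRICT)
        & (df["nes"] > NES_MIN)
        & (df["leading_edge_signal"] > LEADING_EDGE_MIN)
    )
    df["significant_tcga_rule"] = df["fdr"] <= FDR_LENIENT
    return df[["es", "nes", "pval", "fdr", "n_genes", "leading_edge_signal",
               "leading_edge_genes", "significant_cellline_rule",
               "significant_tcga_rule"]]


@dataclass
class VipScores:
    vip: pd.Series  # gene -> VIP >= 0
    n_components: int


def plsda_vip(
    expr_a: ExpressionProfile,
    expr_b: ExpressionProfile,
    n_components: int = 2,
    scale: bool = True,
) -> VipScores:
    """PLS-DA variable importance in projection for every gene.

    Fits PLS regression of dummy-coded class membership (A = 1, B = 0) on
    autoscaled expression and computes VIP over the fitted components.
    sum VIP^2 equals the gene count (unit-norm weights).
    """
    X, labels = _stack(expr_a, expr_b)
    if len(np.unique(labels)) < 2:
        raise ValueError("PLS-DA needs samples from both classes")
    n_samples = X.shape[1]
    if n_samples < n_components + 1:
        raise ValueError(
            f"{n_samples} samples cannot support {n_components} components"
        )
    Xs = X.to_numpy(dtype=float).T  # samples x genes
    pls = PLSRegression(n_components=n_components, scale=scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual warnings on tiny n
        pls.fit(Xs, labels)
    W = pls.x_weights_  # (p, a), unit-norm columns
    T = pls.x_scores_  # (n, a)
    q = pls.y_loadings_.ravel()  # (a,)
    ss = (q**2) * (T**2).sum(axis=0)  # class variance explained per component
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 @ ss) / ss.sum())
    return VipScores(vip=pd.Series(vip, index=X.index, name="vip"),
                     n_components=n_components)


def select_signature(
    vip: VipScores, threshold: float = VIP_THRESHOLD
) -> List[str]:
    """Genes with VIP >= threshold (inclusive), most important first."""
    sel = vip.vip[vip.vip >= threshold].sort_values(ascending=False)
    if sel.empty:
        warnings.warn(
            f"no gene reaches VIP >= {threshold}; signature is empty",
            stacklevel=2,
        )
    return list(sel.index)


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read a GMT gene-set collection."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(path)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str,
              description: str = "imatpipe") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
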