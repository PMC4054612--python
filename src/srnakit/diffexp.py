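"""Differential expression of small RNA counts between two matched groups.

The model follows the classic DESeq negative-binomial framework:

* library depth by median-of-ratios size factors ``s_j``;
* per-feature dispersion ``alpha_i`` by method of moments on the pooled
  within-group variance of normalised counts, with a ``a0 + a1/mu`` trend
  fitted across features and the conservative ``max(empirical, fitted)``
  sharing rule, so ``Var = mu + alpha * mu^2``;
* a two-group exact test that conditions on the total count
  ``K_S = K_A + K_B`` and sums the probabilities of all splits
  ``(a, b), a + b = K_S`` that are no more likely than the observed one,
  normalised by the total probability of the splits;
* Benjamini-Hochberg control of the false discovery rate (threshold 0.1).

Sample-level quality control precedes testing: principal component
analysis of ``log2(NEV + 1)`` flags any library four or more standard
deviations from the mean score on PC1 or PC2, and removes it together
with its patient-matched partner.

The public surface is statsmodels-flavoured: build a
:class:`SmallRNADEModel` from a count matrix, call :meth:`fit`, and read
estimates and diagnostics off the returned :class:`SmallRNADEResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .quantify import log2_fold_change, normalize, size_factors

__all__ = [
    "OutlierReport",
    "DispersionModel",
    "SmallRNADEModel",
    "SmallRNADEResults",
    "pca_outliers",
    "estimate_dispersions",
    "nb_exact_test",
    "bh_fdr",
    "size_factors",
    "ma_table",
    "cluster_samples_newick",
    "boxplot_table",
]


# ---------------------------------------------------------------------------
# PCA outlier detection
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    scores: pd.DataFrame          # samples x (PC1, PC2)
    means: pd.Series              # per-PC mean of sample scores
    sds: pd.Series                # per-PC population SD of sample scores
    flagged: list[str]            # samples >= outlier_sd SDs from the mean
    removed: list[str]            # flagged plus their patient partners
    degenerate: bool = False


def pca_outliers(
    nev: pd.DataFrame,
    outlier_sd: float = 4.0,
    pairs: Mapping[str, str] | None = None,
    log_transform: bool = True,
) -> OutlierReport:
    """Flag outlying libraries on the first two principal components.

    PCA is run on ``log2(NEV + 1)`` with features centred; a sample whose
    score on PC1 or PC2 deviates from the mean score by at least
    ``outlier_sd`` population standard deviations is flagged, and both
    samples of a flagged patient are removed.
    """
    samples = list(nev.columns)
    if len(samples) < 4:
        raise ValueError(f"PCA outlier detection needs >= 4 samples, got {len(samples)}")
    X = nev.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        X = np.log2(X + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        warnings.warn("degenerate PCA: no variance between samples; no outliers")
        scores = pd.DataFrame(0.0, index=samples, columns=["PC1", "PC2"])
        zero = pd.Series(0.0, index=["PC1", "PC2"])
        return OutlierReport(scores, zero, zero.copy(), [], [], degenerate=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(2, S.size)
    sc = U[:, :k] * S[:k]
    if k < 2:
        sc = np.hstack([sc, np.zeros((len(samples), 1))])
    scores = pd.DataFrame(sc[:, :2], index=samples, columns=["PC1", "PC2"])
    means = scores.mean()
    sds = scores.std(ddof=0)
    flagged: list[str] = []
    for sample in samples:
        for pc in ("PC1", "PC2"):
            sd = sds[pc]
            if sd > 0 and abs(scores.loc[sample, pc] - means[pc]) >= outlier_sd * sd:
                flagged.append(sample)
                break
    removed = set(flagged)
    if pairs:
        patients = {p for s, p in pairs.items() if s in removed}
        removed |= {s for s, p in pairs.items() if p in patients}
    return OutlierReport(scores, means, sds, flagged, sorted(removed))


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    raw: pd.Series                # method-of-moments alpha-hat per feature
    base_mean: pd.Series          # mean normalised count per feature
    trend_a0: float
    trend_a1: float
    final: pd.Series              # max(raw, trend) per feature

    def trend(self, mu):
        with np.errstate(divide="ignore"):
            return np.maximum(self.trend_a0 + self.trend_a1 / np.asarray(mu, float), 0.0)


def estimate_dispersions(
    counts: pd.DataFrame,
    s: pd.Series,
    groups: Mapping[str, str],
) -> DispersionModel:
    """Method-of-moments NB dispersions with a 1/mu trend and
    ``max(empirical, fitted)`` sharing."""
    labels = pd.Series({lib: groups[lib] for lib in counts.columns})
    sizes = labels.value_counts()
    if (sizes < 2).any():
        bad = ", ".join(sizes[sizes < 2].index)
        raise ValueError(f"need >= 2 replicates per group; group(s) {bad} too small")
    s = s.reindex(counts.columns)
    q = counts.div(s, axis=1)  # normalised counts
    mu = q.mean(axis=1)
    xim = float((1.0 / s).mean())  # shot-noise scale

    # pooled within-group variance of normalised counts
    num = pd.Series(0.0, index=counts.index)
    dof = 0
    for g in sizes.index:
        cols = labels[labels == g].index
        num += q[cols].var(axis=1, ddof=1) * (len(cols) - 1)
        dof += len(cols) - 1
    w = num / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - xim * mu) / (mu**2)
    raw = raw.where(mu > 0, 0.0).clip(lower=0.0).fillna(0.0)

    fit_mask = (raw > 0) & (mu > 0)
    if fit_mask.sum() >= 2:
        A = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask].to_numpy()])
        coef, *_ = np.linalg.lstsq(A, raw[fit_mask].to_numpy(), rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = 0.0, 0.0
    model = DispersionModel(raw, mu, a0, a1, raw.copy())
    fitted = pd.Series(model.trend(mu.to_numpy()), index=counts.index).where(mu > 0, 0.0)
    model.final = np.maximum(raw, fitted).clip(lower=0.0)
    return model


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def _group_pmf(mean: float, var: float):
    """PMF over counts for a group total with the given mean/variance
    (NB when overdispersed, Poisson in the limit)."""
    if var <= mean * (1 + 1e-12):
        return lambda k: stats.poisson.pmf(k, mean)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return lambda k: stats.nbinom.pmf(k, r, p)


def nb_exact_test(
    counts_i: pd.Series | Mapping[str, float],
    s: pd.Series | Mapping[str, float],
    groups: Mapping[str, str],
    alpha: float,
    group_labels: tuple[str, str] | None = None,
) -> float:
    """Two-group NB exact test for one feature.

    Group totals are rounded half-to-even to integers; under the null the
    pooled per-unit-size-factor mean is ``mu = K_S / sum(s)``, each group
    total has mean ``mu * S_g`` and variance
    ``mu * S_g + alpha * mu^2 * sum_{j in g} s_j^2``, and the p-value sums
    the probabilities of all splits at most as likely as the observed one,
    normalised over all splits of ``K_S``.
    """
    counts_i = pd.Series(counts_i, dtype=float)
    s = pd.Series(s, dtype=float).reindex(counts_i.index)
    lab = pd.Series({lib: groups[lib] for lib in counts_i.index})
    if group_labels is None:
        group_labels = tuple(sorted(lab.unique()))
    if len(group_labels) != 2:
        raise ValueError(f"exact test needs exactly two groups, got {group_labels}")
    gA, gB = group_labels
    colsA, colsB = lab[lab == gA].index, lab[lab == gB].index
    KA = int(np.rint(counts_i[colsA].sum()))
    KB = int(np.rint(counts_i[colsB].sum()))
    KS = KA + KB
    if KS == 0:
        return 1.0
    SA, SB = float(s[colsA].sum()), float(s[colsB].sum())
    S2A, S2B = float((s[colsA] ** 2).sum()), float((s[colsB] ** 2).sum())
    mu = KS / (SA + SB)
    pmfA = _group_pmf(mu * SA, mu * SA + alpha * mu * mu * S2A)
    pmfB = _group_pmf(mu * SB, mu * SB + alpha * mu * mu * S2B)
    a = np.arange(KS + 1)
    prob = pmfA(a) * pmfB(KS - a)
    total = prob.sum()
    if total <= 0:
        return 1.0
    obs = prob[KA]
    p = prob[prob <= obs * (1 + 1e-8)].sum() / total
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_fdr(pvalues: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any(np.isnan(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index)
    return adj


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SmallRNADEModel:
    """Two-group NB exact-test differential expression model.

    Parameters
    ----------
    counts : DataFrame
        Fractional counts, features x libraries.
    groups : mapping
        Library -> group label; ``control``/``case`` name the two labels.
    pairs : mapping, optional
        Library -> patient id for the matched design; used only to remove
        the partner of a flagged outlier.
    nev : DataFrame, optional
        Normalised expression values for reporting; defaults to
        reads-per-million of ``counts``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: Mapping[str, str],
        control: str = "N",
        case: str = "C",
        pairs: Mapping[str, str] | None = None,
        nev: pd.DataFrame | None = None,
    ):
        self.counts = counts.astype(float)
        self.groups = dict(groups)
        self.control, self.case = control, case
        self.pairs = dict(pairs) if pairs else None
        self.nev = nev if nev is not None else normalize(self.counts, "rpm")
        self.outlier_report: OutlierReport | None = None

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, control_prefix: str = "N", case_prefix: str = "C", **kw
    ) -> "SmallRNADEModel":
        """Infer groups and patient pairs from column names like N1/C1."""
        groups = {
            c: (control_prefix if c.startswith(control_prefix) else case_prefix)
            for c in counts.columns
        }
        pairs = {c: c.lstrip(control_prefix + case_prefix) for c in counts.columns}
        return cls(counts, groups, control=control_prefix, case=case_prefix, pairs=pairs, **kw)

    def remove_outliers(
        self, outlier_sd: float = 4.0, log_transform: bool = True
    ) -> OutlierReport:
        """Single-pass PCA outlier exclusion (flagged samples and their
        patient partners are dropped from the model in place)."""
        report = pca_outliers(self.nev, outlier_sd, self.pairs, log_transform)
        if report.removed:
            keep = [c for c in self.counts.columns if c not in report.removed]
            self.counts = self.counts[keep]
            self.nev = self.nev[keep]
            self.groups = {k: v for k, v in self.groups.items() if k in keep}
            if self.pairs:
                self.pairs = {k: v for k, v in self.pairs.items() if k in keep}
        self.outlier_report = report
        return report

    def fit(self, de_fdr: float = 0.1, pseudo_nev: float = 0.1) -> "SmallRNADEResults":
        s = size_factors(self.counts)
        disp = estimate_dispersions(self.counts, s, self.groups)
        labels = pd.Series(self.groups)
        ctrl_cols = labels[labels == self.control].index
        case_cols = labels[labels == self.case].index

        pvals = pd.Series(
            {
                f: nb_exact_test(
                    self.counts.loc[f],
                    s,
                    self.groups,
                    float(disp.final[f]),
                    group_labels=(self.control, self.case),
                )
                for f in self.counts.index
            }
        )
        fdr = bh_fdr(pvals)
        ctrl_nev = self.nev[ctrl_cols].mean(axis=1)
        case_nev = self.nev[case_cols].mean(axis=1)
        lfc = pd.Series(
            {
                f: log2_fold_change(ctrl_nev[f], case_nev[f], pseudo=pseudo_nev)
                for f in self.counts.index
            }
        )
        direction = pd.Series("ns", index=self.counts.index)
        sig = fdr < de_fdr
        direction[sig & (lfc > 0)] = "up"
        direction[sig & (lfc < 0)] = "down"
        table = pd.DataFrame(
            {
                "feature": self.counts.index,
                "control_nev": ctrl_nev,
                "cancer_nev": case_nev,
                "log2_fold_change": lfc,
                "pvalue": pvals,
                "fdr": fdr,
                "direction": direction,
            }
        ).set_index("feature")
        return SmallRNADEResults(self, table, s, disp, de_fdr)


@dataclass
class SmallRNADEResults:
    """Fit results: per-feature estimates plus model diagnostics."""

    model: SmallRNADEModel
    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: DispersionModel
    de_fdr: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.de_fdr]

    def summary(self, top: int = 15) -> str:
        """Table-style text summary: top down- and upregulated features."""
        lines = [
            "Small RNA differential expression (NB exact test)",
            f"libraries: {len(self.model.counts.columns)}  features: {len(self.table)}  "
            f"significant at FDR<{self.de_fdr:g}: {len(self.significant)}",
            "",
        ]
        for direction in ("down", "up"):
            sub = (
                self.table[self.table["direction"] == direction]
                .sort_values("fdr")
                .head(top)
            )
            lines.append(f"Top {min(top, len(sub))} {direction}regulated:")
            if len(sub):
                lines.append(
                    sub.to_string(
                        float_format=lambda v: f"{v:.4g}",
                        columns=["control_nev", "cancer_nev", "log2_fold_change", "fdr"],
                    )
                )
            lines.append("")
        return "\n".join(lines)

    def ma_table(self) -> pd.DataFrame:
        return ma_table(self.table, self.model.nev, self.de_fdr)

    def cluster_newick(self) -> str | None:
        return cluster_samples_newick(self.model.nev, list(self.significant.index))

    def boxplot_table(self) -> pd.DataFrame:
        return boxplot_table(self.model.nev, self.model.groups, self.table, self.de_fdr)


# ---------------------------------------------------------------------------
# Summaries (MA data, clustering, boxplot data)
# ---------------------------------------------------------------------------

def ma_table(de_table: pd.DataFrame, nev: pd.DataFrame, de_fdr: float = 0.1) -> pd.DataFrame:
    """MA data: mean log2 NEV vs log2 fold change, flagged at FDR < 0.1."""
    mean_log = np.log2(nev + 1.0).mean(axis=1)
    return pd.DataFrame(
        {
            "mean_log2_nev": mean_log.reindex(de_table.index),
            "log2_fold_change": de_table["log2_fold_change"],
            "significant": de_table["fdr"] < de_fdr,
        }
    )


def _tree_to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _tree_to_newick(node.left, names)
    right = _tree_to_newick(node.right, names)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_samples_newick(nev: pd.DataFrame, features: list[str]) -> str | None:
    """Average-linkage clustering of samples on the given features with
    1 - Pearson distance, as a Newick string (None if < 2 features)."""
    if len(features) < 2:
        warnings.warn("fewer than 2 significant features; clustering skipped")
        return None
    X = np.log2(nev.loc[features] + 1.0).to_numpy(dtype=float).T  # samples x feats
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(Z)
    return _tree_to_newick(tree, list(nev.columns)) + ";"


def significance_stars(fdr: float) -> str:
    if fdr < 0.01:
        return "**"
    if fdr < 0.05:
        return "*"
    return ""


def boxplot_table(
    nev: pd.DataFrame,
    groups: Mapping[str, str],
    de_table: pd.DataFrame,
    de_fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-feature per-group NEV quartiles for significant features, with
    significance stars (** FDR < 0.01, * FDR < 0.05)."""
    labels = pd.Series(groups)
    rows = []
    for f in de_table.index[de_table["fdr"] < de_fdr]:
        for g in sorted(labels.unique()):
            vals = nev.loc[f, labels[labels == g].index].astype(float)
            q = np.percentile(vals, [0, 25, 50, 75, 100])
            rows.append(
                {
                    "feature": f,
                    "group": g,
                    "min": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "max": q[4],
                    "stars": significance_stars(float(de_table.loc[f, "fdr"])),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "group", "min", "q1", "median", "q3", "max", "stars"])
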