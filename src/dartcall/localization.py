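"""Paired soma/neurite localization statistics.

Gene-level fragment counts from neurite samples are paired with the soma
sample from the same culture insert.  Enrichment (FC_N/S) is estimated per
condition with a negative-binomial GLM of counts on compartment, blocking
on the insert; changes in localization between conditions (delta FC_N/S)
follow a dual-pipeline procedure: (i) a compartment x condition interaction
test and (ii) a test on within-pair neurite/soma ratios across conditions.
For every gene the LESS significant pipeline (the larger p-value) supplies
the final p-value, which is then BH-adjusted.

Normalization is median-of-ratios; NB dispersions are method-of-moments
estimates shrunk toward a mean-dispersion trend and shared across
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .editing_stats import adjust_fdr

LOG2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

SAMPLE_COLUMNS = ["sample_id", "compartment", "condition", "pair_id"]


@dataclass
class CountMatrix:
    """Gene x sample integer fragment counts plus the sample sheet.

    ``samples`` must carry compartment (soma/neurite), condition and pair_id
    per sample; every neurite sample needs exactly one soma partner with the
    same pair_id.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.samples = self.samples.set_index("sample_id") if (
            "sample_id" in self.samples.columns
        ) else self.samples
        missing = set(self.samples.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"samples without counts: {sorted(missing)}")
        self.counts = self.counts[list(self.samples.index)]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for pair, grp in self.samples.groupby("pair_id"):
            comps = sorted(grp["compartment"])
            if comps != ["neurite", "soma"]:
                raise ValueError(
                    f"pair {pair!r} must have exactly one soma and one neurite sample"
                )

    def subset(self, condition=None) -> "CountMatrix":
        s = self.samples
        if condition is not None:
            s = s[s["condition"] == condition]
        return CountMatrix(self.counts[list(s.index)], s.reset_index())


@dataclass
class EnrichmentResult:
    gene_id: str
    base_mean: float
    log2_fc_ns: float
    p_value: float
    q_value: float
    label: str


@dataclass
class DeltaLocalizationResult:
    gene_id: str
    delta_log2_fc_ns: float
    p_pipeline1: float
    p_pipeline2: float
    p_final: float
    q_value: float = np.nan


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (DESeq-style contract)."""
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a "
            "pseudo-reference normalization"
        )
    logm = np.log(mat[all_pos])
    log_geo = logm.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logm - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments within sample groups,
    shrunk toward a 1/mean trend fitted across genes, floored at 1e-8.

    The gene-wise moment estimate at small replicate numbers is extremely
    noisy, so it enters with a weight that grows with the residual degrees
    of freedom (dof/(dof+20)); genes whose raw estimate is undefined fall
    back to the trend entirely."""
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    if groups is None:
        grp_codes = np.zeros(norm.shape[1], dtype=int)
    else:
        grp_codes = pd.Categorical(groups.loc[counts.columns]).codes
    mean = norm.mean(axis=1)
    # pooled within-group variance
    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in np.unique(grp_codes):
        sub = norm[:, grp_codes == g]
        if sub.shape[1] >= 2:
            ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            dof += sub.shape[1] - 1
    if dof == 0:
        raise ValueError("need >=2 replicates in at least one group")
    pooled_var = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (pooled_var - mean) / np.maximum(mean, 1e-12) ** 2, np.nan)
    ok = np.isfinite(raw) & (mean > 0)
    clipped = np.clip(raw[ok], -1.0, 10.0)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, clipped, rcond=None)
    trend = np.maximum(coef[0] + coef[1] / np.maximum(mean, 1e-12), DISPERSION_FLOOR)
    gene = np.maximum(np.where(np.isfinite(raw), raw, trend), 0.0)
    w = dof / (dof + 20.0)
    shrunk = w * gene + (1.0 - w) * trend
    return pd.Series(
        np.maximum(shrunk, DISPERSION_FLOOR), index=counts.index, name="dispersion"
    )


def _nb_wald(y, X, offset, alpha, term: int):
    """Wald estimate/p for one coefficient of an NB GLM with known alpha."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=fam, offset=offset).fit(tol=1e-10, maxiter=200)
        except Exception:
            return np.nan, np.nan
    est = float(fit.params[term])
    se = float(fit.bse[term])
    if not np.isfinite(se) or se <= 0:
        return est, np.nan
    z = est / se
    return est, float(2.0 * stats.norm.sf(abs(z)))


def _design_paired(meta: pd.DataFrame) -> np.ndarray:
    """Intercept + compartment + pair blocking dummies (one condition)."""
    comp = (meta["compartment"] == "neurite").to_numpy(float)
    pairs = sorted(meta["pair_id"].unique())
    dummies = [
        (meta["pair_id"] == p).to_numpy(float) for p in pairs[1:]
    ]  # first pair is reference
    return np.column_stack([np.ones(len(meta)), comp] + dummies)


def fc_ns(
    cm: CountMatrix,
    condition: str,
    mito_genes: set[str] | frozenset = frozenset(),
    fold: float = 1.5,
    fdr: float = 0.05,
    base_mean_min: float = 10.0,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene neurite/soma enrichment within one condition.

    NB GLM of counts on compartment with the culture insert as a blocking
    covariate; Wald p on the compartment coefficient, BH q.  Genes with
    baseMean < ``base_mean_min`` or on the mitochondrial contig are labeled
    ``filtered`` and excluded from testing.
    """
    sub = cm.subset(condition=condition)
    meta = sub.samples
    if meta["pair_id"].nunique() < 2:
        raise ValueError("need >=2 soma/neurite pairs")
    if sf is None:
        sf = size_factors(sub.counts)
    sf = sf.loc[sub.counts.columns]
    if dispersions is None:
        grp = meta["compartment"]
        dispersions = estimate_dispersion(sub.counts, sf, groups=grp)
    base_mean = (sub.counts.to_numpy(float) / sf.to_numpy()[None, :]).mean(axis=1)
    X = _design_paired(meta)
    offset = np.log(sf.to_numpy())
    rows = []
    for i, gene in enumerate(sub.counts.index):
        testable = base_mean[i] >= base_mean_min and gene not in mito_genes
        if not testable:
            rows.append((gene, base_mean[i], np.nan, np.nan, "filtered"))
            continue
        y = sub.counts.loc[gene].to_numpy(float)
        est, p = _nb_wald(y, X, offset, dispersions.loc[gene], term=1)
        rows.append((gene, base_mean[i], est / LOG2, p, ""))
    df = pd.DataFrame(
        rows, columns=["gene_id", "base_mean", "log2_fc_ns", "p_value", "label"]
    )
    tested = df["label"] != "filtered"
    q = np.full(len(df), np.nan)
    pvals = df.loc[tested, "p_value"].fillna(1.0)
    q[tested.to_numpy()] = adjust_fdr(pvals)
    df["q_value"] = q
    lf = np.log2(fold)
    sig = tested & (df["q_value"] <= fdr)
    df.loc[tested, "label"] = "none"
    df.loc[sig & (df["log2_fc_ns"] >= lf), "label"] = "neurite_enriched"
    df.loc[sig & (df["log2_fc_ns"] <= -lf), "label"] = "neurite_depleted"
    return df


def _design_interaction(meta: pd.DataFrame, cond_b: str):
    comp = (meta["compartment"] == "neurite").to_numpy(float)
    cond = (meta["condition"] == cond_b).to_numpy(float)
    inter = comp * cond
    dummies = []
    for c in sorted(meta["condition"].unique()):
        pairs = sorted(meta.loc[meta["condition"] == c, "pair_id"].unique())
        for p in pairs[1:]:  # one reference pair per condition
            dummies.append((meta["pair_id"] == p).to_numpy(float))
    X = np.column_stack([np.ones(len(meta)), comp, cond, inter] + dummies)
    return X, 3


def delta_fc_ns(
    cm: CountMatrix,
    cond_a: str,
    cond_b: str,
    mito_genes: set[str] | frozenset = frozenset(),
    base_mean_min: float = 10.0,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Change in neurite enrichment between conditions (delta FC_N/S).

    Pipeline 1 tests the compartment x condition interaction in a single NB
    GLM over all samples (pair-blocked).  Pipeline 2 models each pair's
    neurite count with the paired normalized soma count as offset and tests
    the condition effect on that within-pair ratio.  Per gene the larger
    (least significant) p-value is final; the reported effect is the
    interaction estimate in log2 units.
    """
    meta = cm.samples
    for cond in (cond_a, cond_b):
        comps = set(meta.loc[meta["condition"] == cond, "compartment"])
        if comps != {"soma", "neurite"}:
            raise ValueError(f"condition {cond!r} lacks a compartment")
    keep = meta["condition"].isin([cond_a, cond_b])
    sub = CountMatrix(cm.counts[list(meta.index[keep])], meta[keep].reset_index())
    meta = sub.samples
    if sf is None:
        sf = size_factors(sub.counts)
    sf = sf.loc[sub.counts.columns]
    if dispersions is None:
        grp = meta["compartment"].astype(str) + "/" + meta["condition"].astype(str)
        dispersions = estimate_dispersion(sub.counts, sf, groups=grp)
    base_mean = (sub.counts.to_numpy(float) / sf.to_numpy()[None, :]).mean(axis=1)

    X1, term1 = _design_interaction(meta, cond_b)
    offset1 = np.log(sf.to_numpy())

    neur = meta[meta["compartment"] == "neurite"]
    soma = meta[meta["compartment"] == "soma"].reset_index().set_index("pair_id")
    neur_samples = list(neur.index)
    soma_partner = [soma.loc[neur.loc[s, "pair_id"], "sample_id"] for s in neur_samples]
    cond2 = (neur["condition"] == cond_b).to_numpy(float)
    X2 = np.column_stack([np.ones(len(neur_samples)), cond2])
    sf_n = sf.loc[neur_samples].to_numpy()
    sf_s = sf.loc[soma_partner].to_numpy()

    results = []
    for i, gene in enumerate(sub.counts.index):
        if base_mean[i] < base_mean_min or gene in mito_genes:
            continue
        y = sub.counts.loc[gene].to_numpy(float)
        est, p1 = _nb_wald(y, X1, offset1, dispersions.loc[gene], term=term1)
        y_n = sub.counts.loc[gene, neur_samples].to_numpy(float)
        y_s = sub.counts.loc[gene, soma_partner].to_numpy(float)
        offset2 = np.log(sf_n) + np.log(y_s / sf_s + 0.5)
        _, p2 = _nb_wald(y_n, X2, offset2, dispersions.loc[gene], term=1)
        p1 = 1.0 if not np.isfinite(p1) else p1
        p2 = 1.0 if not np.isfinite(p2) else p2
        results.append(
            DeltaLocalizationResult(gene, est / LOG2, p1, p2, max(p1, p2))
        )
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "delta_log2_fc_ns": [r.delta_log2_fc_ns for r in results],
            "p_pipeline1": [r.p_pipeline1 for r in results],
            "p_pipeline2": [r.p_pipeline2 for r in results],
            "p_final": [r.p_final for r in results],
        }
    )
    assert (df["p_final"] >= df["p_pipeline1"] - 1e-15).all()
    assert (df["p_final"] >= df["p_pipeline2"] - 1e-15).all()
    df["q_value"] = adjust_fdr(df["p_final"]) if len(df) else []
    return df


def soma_response(
    cm: CountMatrix,
    cond_a: str,
    cond_b: str,
    fold: float = 2.0,
    fdr: float = 0.05,
    base_mean_min: float = 10.0,
    mito_genes: set[str] | frozenset = frozenset(),
) -> pd.DataFrame:
    """Condition response in the soma fraction only (e.g. KCl induction),
    with the +/-2-fold default threshold."""
    meta = cm.samples
    keep = (meta["compartment"] == "soma") & meta["condition"].isin([cond_a, cond_b])
    counts = cm.counts[list(meta.index[keep])]
    meta = meta[keep]
    sf = size_factors(counts)
    disp = estimate_dispersion(counts, sf, groups=meta["condition"])
    base_mean = (counts.to_numpy(float) / sf.to_numpy()[None, :]).mean(axis=1)
    cond = (meta["condition"] == cond_b).to_numpy(float)
    X = np.column_stack([np.ones(len(meta)), cond])
    offset = np.log(sf.to_numpy())
    rows = []
    for i, gene in enumerate(counts.index):
        if base_mean[i] < base_mean_min or gene in mito_genes:
            rows.append((gene, base_mean[i], np.nan, np.nan, "filtered"))
            continue
        est, p = _nb_wald(counts.loc[gene].to_numpy(float), X, offset,
                          disp.loc[gene], term=1)
        rows.append((gene, base_mean[i], est / LOG2, p, ""))
    df = pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2_fc", "p_value", "label"])
    tested = df["label"] != "filtered"
    q = np.full(len(df), np.nan)
    q[tested.to_numpy()] = adjust_fdr(df.loc[tested, "p_value"].fillna(1.0))
    df["q_value"] = q
    lf = np.log2(fold)
    sig = tested & (df["q_value"] <= fdr)
    df.loc[tested, "label"] = "none"
    df.loc[sig & (df["log2_fc"] >= lf), "label"] = "up"
    df.loc[sig & (df["log2_fc"] <= -lf), "label"] = "down"
    return df


def fpkm(
    counts: pd.DataFrame, exon_lengths: pd.Series, sf: pd.Series | None = None
) -> pd.DataFrame:
    """Fragments per kilobase of union exon per million mapped fragments,
    computed on normalized counts over the normalized library size."""
    lengths = exon_lengths.loc[counts.index].to_numpy(float)
    if np.any(lengths <= 0):
        raise ValueError("exon lengths must be positive")
    if sf is None:
        sf = pd.Series(1.0, index=counts.columns)
    norm = counts.to_numpy(float) / sf.loc[counts.columns].to_numpy()[None, :]
    lib_millions = norm.sum(axis=0) / 1e6
    vals = norm / (lengths[:, None] / 1000.0) / lib_millions[None, :]
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def expressed_in_neurites(
    fpkm_df: pd.DataFrame, samples: pd.DataFrame, threshold: float = 5.0
) -> set[str]:
    """Genes whose replicate-mean neurite FPKM is strictly above threshold."""
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    neur = meta.index[meta["compartment"] == "neurite"]
    mean_fpkm = fpkm_df[list(neur)].mean(axis=1)
    return set(mean_fpkm.index[mean_fpkm > threshold])
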