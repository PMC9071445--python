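"""Differential editing statistics and per-RNA editing scores.

Editing frequencies are compared between two groups (conditions or
compartments) with a binomial GLM on the logit scale: one row per sample of
(edited, unedited) counts regressed on a group indicator, Wald z on the
group coefficient.  Complete separation (a group with no edited or no
unedited reads) falls back to a Haldane-corrected pooled 2x2 estimate and
is flagged.  The per-RNA editing score is the cumulative sum of replicate
mean %C2U over all called sites in the RNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DiffEditResult:
    key: str
    log_odds_delta: float
    wald_z: float
    p_value: float
    group_rates: dict[str, float]
    flags: str = ""
    q_value: float = np.nan


@dataclass
class EditingScore:
    gene_id: str
    sample_group: str
    score: float
    n_sites: int


def _pooled_2x2(edited, unedited, groups, ref, alt, pseudo=0.0):
    e = {g: 0.0 for g in (ref, alt)}
    u = {g: 0.0 for g in (ref, alt)}
    for ei, ui, gi in zip(edited, unedited, groups):
        e[gi] += ei
        u[gi] += ui
    cells = [e[ref] + pseudo, u[ref] + pseudo, e[alt] + pseudo, u[alt] + pseudo]
    lod = np.log(cells[2] / cells[3]) - np.log(cells[0] / cells[1])
    se = np.sqrt(sum(1.0 / c for c in cells))
    return lod, se, e, u


def site_differential(
    key: str,
    edited,
    unedited,
    groups,
    contrast: tuple[str, str] | None = None,
    pooled: bool = False,
) -> DiffEditResult:
    """Two-group binomial GLM Wald test for one site (or one pooled gene).

    ``contrast`` is (reference, alternative); the reported log-odds delta is
    alternative minus reference.  With ``pooled`` the per-group counts are
    summed into a 2x2 before fitting (the closed-form special case);
    otherwise each sample is an independent binomial observation.
    """
    edited = np.asarray(edited, dtype=float)
    unedited = np.asarray(unedited, dtype=float)
    groups = list(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    ref, alt = contrast if contrast is not None else (labels[0], labels[1])
    if (edited + unedited <= 0).all():
        raise ValueError("no informative samples")

    tot_e = {g: edited[np.array(groups) == g].sum() for g in (ref, alt)}
    tot_u = {g: unedited[np.array(groups) == g].sum() for g in (ref, alt)}
    rates = {
        g: 100.0 * tot_e[g] / (tot_e[g] + tot_u[g]) if tot_e[g] + tot_u[g] > 0 else np.nan
        for g in (ref, alt)
    }
    separated = any(tot_e[g] == 0 or tot_u[g] == 0 for g in (ref, alt))
    if separated:
        lod, se, _, _ = _pooled_2x2(edited, unedited, groups, ref, alt, pseudo=0.5)
        z = lod / se
        p = 2.0 * stats.norm.sf(abs(z))
        return DiffEditResult(key, lod, z, p, rates, flags="separation")

    if pooled:
        endog = np.array(
            [[tot_e[ref], tot_u[ref]], [tot_e[alt], tot_u[alt]]], dtype=float
        )
        exog = sm.add_constant(np.array([0.0, 1.0]))
    else:
        ind = np.array([1.0 if g == alt else 0.0 for g in groups])
        endog = np.column_stack([edited, unedited])
        exog = sm.add_constant(ind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
            tol=1e-12, maxiter=200
        )
    lod = float(fit.params[1])
    se = float(fit.bse[1])
    z = lod / se if se > 0 else np.inf * np.sign(lod)
    p = 2.0 * stats.norm.sf(abs(z))
    return DiffEditResult(key, lod, z, min(p, 1.0), rates)


def rna_differential(
    gene_id: str,
    site_counts: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    pooled: bool = False,
) -> DiffEditResult:
    """Gene-level contrast: counts pooled across the gene's called sites.

    ``site_counts`` has one row per (site, sample) with columns sample_id,
    group, edited, unedited.  Counts are summed within each sample across
    sites, then tested exactly like a single site.  Sites shifting in
    opposite directions can cancel at the gene level; that aggregation
    behavior is intentional and documented.
    """
    if site_counts.empty:
        raise ValueError(f"{gene_id}: no called sites")
    per_sample = (
        site_counts.groupby(["sample_id", "group"], as_index=False)[
            ["edited", "unedited"]
        ].sum()
    )
    return site_differential(
        gene_id,
        per_sample["edited"],
        per_sample["unedited"],
        per_sample["group"],
        contrast=contrast,
        pooled=pooled,
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def editing_score(
    gene_id: str, site_rates: pd.DataFrame, sample_group: str
) -> EditingScore:
    """Cumulative %C2U over called sites: score = sum of per-site replicate
    mean rates (percentage points), 0 for a gene without sites.

    ``site_rates`` has one row per (site, replicate) with columns site and
    rate (percent) for the replicates of ``sample_group``.
    """
    if site_rates.empty:
        return EditingScore(gene_id, sample_group, 0.0, 0)
    means = site_rates.groupby("site")["rate"].mean()
    return EditingScore(gene_id, sample_group, float(means.sum()), int(means.size))


def differential_table(results: list[DiffEditResult]) -> pd.DataFrame:
    """Assemble results, attach BH q-values, return a tidy frame."""
    df = pd.DataFrame(
        {
            "key": [r.key for r in results],
            "log_odds_delta": [r.log_odds_delta for r in results],
            "wald_z": [r.wald_z for r in results],
            "p_value": [r.p_value for r in results],
            "flags": [r.flags for r in results],
        }
    )
    df["q_value"] = adjust_fdr(df["p_value"]) if len(df) else []
    for r, q in zip(results, df["q_value"] if len(df) else []):
        r.q_value = float(q)
    return df
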