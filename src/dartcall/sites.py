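"""The Bullseye-style m6A site-calling cascade.

Candidate C-to-U sites are called per DART sample against every
methyltransferase-knockout (KO) control, merged across biological
replicates, restricted to the RAC consensus on the transcript strand, and
finally reduced to high-confidence sites whose replicate-mean %C2U exceeds
the KO mean by a configurable fold.

A site is identified by (chrom, pos_c, strand) where pos_c is the edited
cytidine; the inferred methylated adenosine pos_a sits one base 5' of it in
transcript orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, GenomeSequence
from .pileup import EditingTable

log = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "strand"]
RAC_RE = re.compile(r"^[AG]AC$")


@dataclass
class CallParams:
    """Thresholds of the calling cascade.

    Defaults are the published cascade: >=50 unique reads, >=3 edited
    reads, 1-95 %C2U, >=1.25-fold over every adequately covered KO control,
    sites in >=2 replicates, and a 1.5-fold replicate-mean WT/KO ratio for
    the high-confidence set.  ``min_control_coverage`` guards the fold
    comparison against essentially uncovered controls.
    """

    min_coverage: int = 50
    min_edited: int = 3
    min_rate_pct: float = 1.0
    max_rate_pct: float = 95.0
    fold_vs_each_control: float = 1.25
    min_replicates: int = 2
    high_conf_fold: float = 1.5
    min_control_coverage: int = 10

    def validate(self) -> None:
        if not (0 <= self.min_rate_pct < self.max_rate_pct <= 100):
            raise ValueError("need 0 <= min_rate_pct < max_rate_pct <= 100")
        if self.fold_vs_each_control < 1 or self.high_conf_fold < 1:
            raise ValueError("fold thresholds must be >= 1")
        if self.min_coverage < 0 or self.min_edited < 0 or self.min_replicates < 1:
            raise ValueError("count thresholds must be non-negative")


@dataclass
class Site:
    """One called site, for record-oriented consumers of the table API."""

    chrom: str
    pos_c: int
    pos_a: int
    strand: str
    gene_id: str
    motif: str
    mean_rate_wt: float
    mean_rate_ko: float
    n_replicates_called: int
    high_confidence: bool
    flags: str = ""
    replicate_counts: dict = field(default_factory=dict)


def call_candidates(
    dart: EditingTable, controls: list[EditingTable], params: CallParams
) -> pd.DataFrame:
    """Positions in one DART sample passing all per-sample filters.

    A position passes iff coverage >= min_coverage, edited >= min_edited,
    rate within [min_rate_pct, max_rate_pct], and rate >= fold * control
    rate for EVERY control covered at >= min_control_coverage there;
    positions no control covers adequately are rejected.
    """
    params.validate()
    if not controls:
        raise ValueError("at least one control table is required")
    df = dart.df
    mask = (
        (df["coverage"] >= params.min_coverage)
        & (df["edited"] >= params.min_edited)
        & (df["rate"] >= params.min_rate_pct)
        & (df["rate"] <= params.max_rate_pct)
    )
    cand = df[mask].copy()
    n_ok = np.zeros(len(cand), dtype=int)
    fold_ok = np.ones(len(cand), dtype=bool)
    for ctrl in controls:
        cdf = ctrl.df[ctrl.df["coverage"] >= params.min_control_coverage]
        merged = cand.merge(
            cdf[SITE_KEY + ["rate"]], on=SITE_KEY, how="left", suffixes=("", "_ctrl")
        )
        covered = merged["rate_ctrl"].notna().to_numpy()
        n_ok += covered
        ratio_ok = (
            merged["rate"].to_numpy()
            >= params.fold_vs_each_control * merged["rate_ctrl"].to_numpy()
        )
        fold_ok &= np.where(covered, ratio_ok, True)
    cand = cand[(n_ok >= 1) & fold_ok]
    return cand.reset_index(drop=True)


def merge_replicates(
    candidates: dict[str, pd.DataFrame],
    tables: dict[str, EditingTable],
    params: CallParams,
) -> pd.DataFrame:
    """Keep sites called in >= min_replicates replicates.

    Per-replicate edited/unedited/rate are attached from every replicate's
    table whether or not that replicate called the site, with a per-sample
    called_<id> flag, so downstream statistics see the full design.
    """
    params.validate()
    if len(candidates) != len(set(candidates)):
        raise ValueError("duplicate sample ids")
    if set(candidates) - set(tables):
        raise ValueError("candidate list without a matching editing table")
    votes: dict[tuple, int] = {}
    meta: dict[tuple, str] = {}
    for sid, cand in candidates.items():
        for row in cand.itertuples(index=False):
            key = (row.chrom, row.pos, row.strand)
            votes[key] = votes.get(key, 0) + 1
            meta[key] = row.gene_id
    kept = sorted(k for k, v in votes.items() if v >= params.min_replicates)
    out = pd.DataFrame(kept, columns=SITE_KEY)
    out["gene_id"] = [meta[k] for k in kept]
    out["n_replicates_called"] = [votes[k] for k in kept]
    for sid in candidates:
        tdf = tables[sid].df.set_index(SITE_KEY)
        called = {
            (r.chrom, r.pos, r.strand) for r in candidates[sid].itertuples(index=False)
        }
        ed, un, rate, was_called = [], [], [], []
        for key in kept:
            if key in tdf.index:
                row = tdf.loc[key]
                ed.append(int(row["edited"]))
                un.append(int(row["unedited"]))
                rate.append(float(row["rate"]))
            else:
                ed.append(0)
                un.append(0)
                rate.append(np.nan)
            was_called.append(key in called)
        out[f"edited_{sid}"] = ed
        out[f"unedited_{sid}"] = un
        out[f"rate_{sid}"] = rate
        out[f"called_{sid}"] = was_called
    return out


def filter_rac(
    sites: pd.DataFrame, genome: GenomeSequence, annotation: GenomeAnnotation | None = None
) -> pd.DataFrame:
    """Keep sites whose transcript-strand 3-mer ending at the C is [AG]AC.

    Adds ``motif`` and ``pos_a`` (the inferred m6A adenosine, one base 5' of
    the C in transcript orientation).  Sites whose context window crosses a
    contig end are dropped with a log entry.
    """
    motifs, pos_a, keep = [], [], []
    for row in sites.itertuples(index=False):
        try:
            ctx = genome.context(row.chrom, row.pos, row.strand, up=2, down=0)
        except (IndexError, KeyError):
            log.info("dropping %s:%d: context beyond contig end", row.chrom, row.pos)
            keep.append(False)
            motifs.append("")
            pos_a.append(-1)
            continue
        motifs.append(ctx)
        pos_a.append(row.pos - 1 if row.strand == "+" else row.pos + 1)
        keep.append(bool(RAC_RE.match(ctx)))
    out = sites.copy()
    out["motif"] = motifs
    out["pos_a"] = pos_a
    return out[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def high_confidence(
    sites: pd.DataFrame,
    wt_tables: dict[str, EditingTable],
    ko_tables: dict[str, EditingTable],
    params: CallParams,
) -> pd.DataFrame:
    """Sites whose replicate-mean WT %C2U is >= high_conf_fold x the KO mean.

    Replicate means are unweighted averages over the tables covering the
    site.  A site no KO table covers gets mean_rate_ko 0 and is retained
    with a ``no-control-coverage`` flag.
    """
    params.validate()
    wt_idx = {sid: t.df.set_index(SITE_KEY)["rate"] for sid, t in wt_tables.items()}
    ko_idx = {sid: t.df.set_index(SITE_KEY)["rate"] for sid, t in ko_tables.items()}

    def mean_rate(key, idx):
        rates = [s.loc[key] for s in idx.values() if key in s.index]
        rates = [r for r in rates if not np.isnan(r)]
        return float(np.mean(rates)) if rates else np.nan

    mw, mk, flags, keep = [], [], [], []
    for row in sites.itertuples(index=False):
        key = (row.chrom, row.pos, row.strand)
        w = mean_rate(key, wt_idx)
        k = mean_rate(key, ko_idx)
        flag = ""
        if np.isnan(k):
            k = 0.0
            flag = "no-control-coverage"
        mw.append(w)
        mk.append(k)
        flags.append(flag)
        keep.append(not np.isnan(w) and w >= params.high_conf_fold * k)
    out = sites.copy()
    out["mean_rate_wt"] = mw
    out["mean_rate_ko"] = mk
    out["flags"] = flags
    out["high_confidence"] = keep
    return out[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def call_sites(
    dart_tables: dict[str, EditingTable],
    ko_tables: dict[str, EditingTable],
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Full cascade: per-replicate candidates -> merge -> RAC -> confidence."""
    params = params or CallParams()
    controls = list(ko_tables.values())
    candidates = {
        sid: call_candidates(t, controls, params) for sid, t in dart_tables.items()
    }
    merged = merge_replicates(candidates, dart_tables, params)
    rac = filter_rac(merged, genome, annotation)
    return high_confidence(rac, dart_tables, ko_tables, params)


def sites_to_records(df: pd.DataFrame) -> list[Site]:
    reps = sorted(c[len("edited_"):] for c in df.columns if c.startswith("edited_"))
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            Site(
                chrom=d["chrom"],
                pos_c=d["pos"],
                pos_a=d["pos_a"],
                strand=d["strand"],
                gene_id=d["gene_id"],
                motif=d["motif"],
                mean_rate_wt=d["mean_rate_wt"],
                mean_rate_ko=d["mean_rate_ko"],
                n_replicates_called=d["n_replicates_called"],
                high_confidence=d["high_confidence"],
                flags=d.get("flags", ""),
                replicate_counts={
                    sid: (d[f"edited_{sid}"], d[f"unedited_{sid}"]) for sid in reps
                },
            )
        )
    return out


def write_bed(df: pd.DataFrame, path) -> None:
    """BED6+ with score = round(mean WT rate x 10)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            score = int(round(row.mean_rate_wt * 10))
            extras = [
                str(row.pos_a),
                f"{row.mean_rate_wt:.4f}",
                f"{row.mean_rate_ko:.4f}",
                str(row.n_replicates_called),
                getattr(row, "flags", "") or ".",
            ]
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        str(row.pos),
                        str(row.pos + 1),
                        f"{row.gene_id}:{row.motif}",
                        str(score),
                        row.strand,
                    ]
                    + extras
                )
                + "\n"
            )
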