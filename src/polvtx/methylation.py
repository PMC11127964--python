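"""Windowed differential-methylation calling from per-cytosine counts.

Counts come from Bismark-style cytosine reports (CG/CHG/CHH contexts).
Cytosines below the coverage floor are dropped, counts are pooled into
non-overlapping windows (500 bp by default), each matched window gets a
two-sided Fisher exact test on the pooled 2x2 table, q-values are
Benjamini-Hochberg within context, and a window is a DMR when q is below
the q threshold AND the methylation-level difference reaches the
percentage-point threshold (25 pp by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeIndex, Interval

DEFAULT_WIN_SIZE = 500
DEFAULT_STEP = 500
DEFAULT_MINCOV = 4
DEFAULT_DIFFERENCE = 25.0  # percentage points
DEFAULT_QVALUE = 0.01

CONTEXTS = ("CG", "CHG", "CHH")


def window_counts(
    records: pd.DataFrame,
    win_size: int = DEFAULT_WIN_SIZE,
    step: int = DEFAULT_STEP,
    mincov: int = DEFAULT_MINCOV,
) -> pd.DataFrame:
    """Pool per-cytosine counts into tiling windows per (window, context).

    Windows anchor at position 0 of each chromosome.  Cytosines with
    coverage < ``mincov`` contribute nothing; windows without any covered
    cytosine are absent from the output.  ``step`` must divide
    ``win_size`` (step == win_size gives non-overlapping tiles).
    """
    if step <= 0 or win_size <= 0:
        raise ValueError("win_size and step must be positive")
    if win_size % step:
        raise ValueError("step must divide win_size")
    df = records.loc[(records["meth"] + records["unmeth"]) >= mincov].copy()
    frames = []
    for offset in range(0, win_size, step):
        sub = df[df["pos"] >= offset] if offset else df
        win_start = offset + ((sub["pos"] - offset) // win_size) * win_size
        grouped = (
            sub.assign(win_start=win_start)
            .groupby(["chrom", "win_start", "context"], sort=True)
            .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"), n_cytosines=("pos", "size"))
            .reset_index()
        )
        frames.append(grouped)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"win_start": "start"})
    out["end"] = out["start"] + win_size
    out["level"] = out["meth"] / (out["meth"] + out["unmeth"])
    return out.sort_values(["chrom", "start", "context"]).reset_index(drop=True)[
        ["chrom", "start", "end", "context", "meth", "unmeth", "n_cytosines", "level"]
    ]


def call_dmrs(
    test_windows: pd.DataFrame,
    ref_windows: pd.DataFrame,
    difference_threshold: float = DEFAULT_DIFFERENCE,
    q_threshold: float = DEFAULT_QVALUE,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fisher-exact windowed DMR calling between a test and reference sample.

    Returns ``(table, skipped)``: the full per-window table (counts, level
    difference in percentage points as test - reference, p, q, direction
    and the DMR flag) and the windows present in only one sample.
    "hypo" means the test (mutant) sample is lower than the reference.
    """
    key = ["chrom", "start", "end", "context"]
    merged = test_windows.merge(
        ref_windows, on=key, how="outer", suffixes=("_test", "_ref"), indicator=True
    )
    skipped = merged[merged["_merge"] != "both"][key + ["_merge"]].copy()
    skipped["reason"] = skipped["_merge"].map(
        {"left_only": "missing in reference", "right_only": "missing in test"}
    )
    both = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    for col in ("meth_test", "unmeth_test", "meth_ref", "unmeth_ref"):
        both[col] = both[col].astype(int)
    pvals = np.ones(len(both))
    tables = both[["meth_test", "unmeth_test", "meth_ref", "unmeth_ref"]].to_numpy()
    for i, (mt, ut, mr, ur) in enumerate(tables):
        pvals[i] = stats.fisher_exact([[mt, ut], [mr, ur]], alternative="two-sided")[1]
    both["p"] = pvals
    both["q"] = np.nan
    for ctx, idx in both.groupby("context").groups.items():
        both.loc[idx, "q"] = multipletests(both.loc[idx, "p"], method="fdr_bh")[1]
    level_t = both["meth_test"] / (both["meth_test"] + both["unmeth_test"])
    level_r = both["meth_ref"] / (both["meth_ref"] + both["unmeth_ref"])
    both["difference"] = 100.0 * (level_t - level_r)
    both["direction"] = np.where(both["difference"] < 0, "hypo", "hyper")
    both["is_dmr"] = (both["q"] < q_threshold) & (
        both["difference"].abs() >= difference_threshold
    )
    cols = key + [
        "meth_test", "unmeth_test", "meth_ref", "unmeth_ref",
        "difference", "p", "q", "direction", "is_dmr",
    ]
    return (
        both[cols].sort_values(key).reset_index(drop=True),
        skipped.drop(columns="_merge").reset_index(drop=True),
    )


def region_methylation(
    records: pd.DataFrame,
    regions: Sequence[Interval],
    contexts: Sequence[str] = CONTEXTS,
    mincov: int = DEFAULT_MINCOV,
) -> pd.DataFrame:
    """Weighted methylation level per region and context.

    level = sum(meth) / sum(meth + unmeth) over covered cytosines
    (coverage >= mincov) of the context inside the region; NaN (flagged)
    when a region holds no covered cytosine of that context.
    """
    covered = records.loc[(records["meth"] + records["unmeth"]) >= mincov]
    rows = []
    for i, reg in enumerate(regions):
        inside = covered[
            (covered["chrom"] == reg.chrom)
            & (covered["pos"] >= reg.start)
            & (covered["pos"] < reg.end)
        ]
        for ctx in contexts:
            sub = inside[inside["context"] == ctx]
            m, u = int(sub["meth"].sum()), int(sub["unmeth"].sum())
            level = 100.0 * m / (m + u) if (m + u) else np.nan
            rows.append((i, reg.chrom, reg.start, reg.end, ctx, m, u, level))
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "context", "meth", "unmeth", "level"],
    )


def dmrs_to_bed(table: pd.DataFrame) -> pd.DataFrame:
    """BED-style frame of called DMRs: name = context:direction, score = |diff| pp."""
    dmrs = table[table["is_dmr"]].copy()
    dmrs["name"] = dmrs["context"] + ":" + dmrs["direction"]
    dmrs["score"] = dmrs["difference"].abs().round(2)
    return dmrs[["chrom", "start", "end", "name", "score"]].reset_index(drop=True)
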