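"""Salt-stress expression analysis: FPKM, per-time-point differential
expression against 0 h, salt-responsive selection, and the four trajectory
groups.

The per-time-point test is a replicate-level Welch t-test on log2(FPKM+1),
with fold changes computed on replicate means using a pseudocount of 1 and
Benjamini-Hochberg FDR taken across genes within each time point. A
precomputed differential-expression table (e.g. from a count-based NB
pipeline) can be ingested instead through :func:`ingest_de_table`.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import DECall, TIME_POINTS

LOG2FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.01
PSEUDOCOUNT = 1.0
TREATED_TIMES = (1, 6, 24, 48)


def compute_fpkm(fragments: float, mapped_millions: float, length_kb: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if mapped_millions <= 0 or length_kb <= 0:
        raise ValueError("mapped_millions and length_kb must be positive")
    if fragments < 0:
        raise ValueError("fragments must be nonnegative")
    return fragments / (mapped_millions * length_kb)


def relative_expression_qpcr(ct_target: float, ct_reference: float) -> float:
    """2^-dCT with dCT = CT(target) - CT(reference)."""
    return float(2.0 ** -(ct_target - ct_reference))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch_log_p(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t-test p on log2(FPKM+1) replicates; degenerate cases pinned."""
    lx, ly = np.log2(np.asarray(x, float) + 1), np.log2(np.asarray(y, float) + 1)
    if len(lx) < 2 or len(ly) < 2:
        raise ValueError("need >= 2 replicates on both sides")
    if lx.var(ddof=1) == 0 and ly.var(ddof=1) == 0:
        return 1.0 if np.isclose(lx.mean(), ly.mean()) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical data
        return float(stats.ttest_ind(lx, ly, equal_var=False).pvalue)


def call_de_single(gene_id: str, fpkm_t: np.ndarray, fpkm_0: np.ndarray,
                   time: int) -> tuple[float, float]:
    """(log2fc, p) for one gene at one treated time point vs 0 h."""
    if time == 0:
        raise ValueError("time must be a treated time point")
    lfc = float(np.log2((np.mean(fpkm_t) + PSEUDOCOUNT)
                        / (np.mean(fpkm_0) + PSEUDOCOUNT)))
    return lfc, _welch_log_p(fpkm_t, fpkm_0)


def _verdict(log2fc: float, fdr: float) -> str:
    if fdr <= FDR_THRESHOLD and log2fc >= LOG2FC_THRESHOLD:
        return "up"
    if fdr <= FDR_THRESHOLD and log2fc <= -LOG2FC_THRESHOLD:
        return "down"
    return "ns"


def parse_sample_columns(columns) -> dict[int, list[str]]:
    """Group sample names like ``T06_R2`` by time point."""
    by_time: dict[int, list[str]] = {}
    for col in columns:
        m = re.fullmatch(r"T(\d+)_R(\d+)", col)
        if not m:
            raise ValueError(f"sample column {col!r} does not match Ttt_Rr")
        by_time.setdefault(int(m.group(1)), []).append(col)
    return by_time


def de_scan(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Differential-expression calls for every gene at every treated time.

    Returns a tidy frame (gene_id, time, log2fc, p_value, fdr, verdict);
    FDR is BH-adjusted across genes within each time point.
    """
    by_time = parse_sample_columns(fpkm.columns)
    if 0 not in by_time:
        raise ValueError("no 0 h samples in table")
    base = fpkm[by_time[0]].to_numpy(float)
    frames = []
    for t in sorted(k for k in by_time if k != 0):
        treat = fpkm[by_time[t]].to_numpy(float)
        if treat.shape[1] < 2 or base.shape[1] < 2:
            raise ValueError(f"time {t}: need >= 2 replicates per side")
        lfc = np.log2((treat.mean(axis=1) + PSEUDOCOUNT)
                      / (base.mean(axis=1) + PSEUDOCOUNT))
        pvals = np.array([_welch_log_p(treat[i], base[i])
                          for i in range(len(fpkm))])
        fdr = bh_fdr(pvals)
        frames.append(pd.DataFrame({
            "gene_id": fpkm.index, "time": t, "log2fc": lfc,
            "p_value": pvals, "fdr": fdr,
            "verdict": [_verdict(l, f) for l, f in zip(lfc, fdr)],
        }))
    return pd.concat(frames, ignore_index=True)


def ingest_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Accept an external DE table (gene_id, time, log2fc, fdr); add verdicts."""
    need = {"gene_id", "time", "log2fc", "fdr"}
    if not need.issubset(table.columns):
        raise ValueError(f"external DE table needs columns {sorted(need)}")
    out = table.copy()
    out["verdict"] = [_verdict(l, f) for l, f in zip(out.log2fc, out.fdr)]
    return out


def select_salt_responsive(verdicts: list[str]) -> bool:
    """Responsive when differentially expressed at >= 2 treated time points."""
    if len(verdicts) != len(TREATED_TIMES):
        raise ValueError("need verdicts for all four treated time points")
    return sum(v != "ns" for v in verdicts) >= 2


def assign_trajectory_group(calls: list[DECall]) -> int:
    """Trajectory group for a salt-responsive gene.

    Calls must be ordered 1, 6, 24, 48 HAT. Rules applied in order:
    early-dip-then-rise (2), all-down (1), sustained late upregulation (4),
    otherwise transient/specific upregulation (3).
    """
    if [c.time for c in calls] != list(TREATED_TIMES):
        raise ValueError("calls must be ordered 1, 6, 24, 48 HAT")
    verdicts = [c.verdict for c in calls]
    if not select_salt_responsive(verdicts):
        raise ValueError("gene is not salt-responsive")
    lfc = [c.log2fc for c in calls]
    if verdicts[0] == "down" and all(b >= a for a, b in zip(lfc, lfc[1:])):
        return 2
    if "up" not in verdicts:
        return 1
    if "down" not in verdicts and verdicts[2] == "up" and verdicts[3] == "up":
        return 4
    return 3


def classify_trajectories(de_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene responsiveness flag and group from a tidy DE table."""
    rows = []
    for gid, sub in de_table.groupby("gene_id", sort=True):
        sub = sub.set_index("time").loc[list(TREATED_TIMES)]
        verdicts = sub.verdict.tolist()
        responsive = select_salt_responsive(verdicts)
        group = None
        if responsive:
            calls = [DECall(gid, int(t), float(r.log2fc), float(r.get("p_value", np.nan)),
                            float(r.fdr), r.verdict)
                     for t, r in sub.iterrows()]
            group = assign_trajectory_group(calls)
        rows.append((gid, responsive, group))
    out = pd.DataFrame(rows, columns=["gene_id", "salt_responsive", "group"])
    out["group"] = out.group.astype("Int64")
    return out
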