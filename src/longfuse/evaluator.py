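"""Score fusion calls against simulation truth; benchmark-style metrics.

A truth fusion counts as detected when a call shares its gene pair
(optionally in either order) or reports a breakpoint within 1 kbp Euclidean
distance of the simulated junction. Metrics mirror a coverage x identity
sensitivity grid, the share of detected fusions ranked High Confidence, the
share reported with a single breakpoint, exact-breakpoint resolution, and
supporting-read recovery per identity level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_MATCH_RADIUS = 1000.0


@dataclass
class MatchResult:
    truth_id: str
    call_index: Optional[int]  # row index into the calls table, or None
    distance: float
    exact: bool
    classification: Optional[str]
    n_breakpoints: int  # reported breakpoints for the truth's gene pair


def _bp_distance(call_row, truth_row) -> float:
    if (call_row.chrom5 != truth_row.chrom5
            or call_row.chrom3 != truth_row.chrom3):
        return math.inf
    return math.hypot(call_row.base5 - truth_row.base5,
                      call_row.base3 - truth_row.base3)


def _pair(g5, g3, unordered: bool):
    return frozenset((g5, g3)) if unordered else (g5, g3)


def match_truth(calls: pd.DataFrame, truth: pd.DataFrame,
                radius: float = DEFAULT_MATCH_RADIUS,
                unordered: bool = True) -> list[MatchResult]:
    """Greedy closest-distance matching of truth fusions to calls.

    ``calls`` is the ranked fusion table (columns fusion_genes, chrom/base/
    strand x2, spanning_reads, classification); ``truth`` the simulator's
    fusion-level table. Each truth matches at most one call and vice versa;
    candidate matches share the gene pair or lie within ``radius``. Ties are
    broken by call rank (row order).
    """
    call_pairs = []
    for idx, row in calls.iterrows():
        g5, g3 = row.fusion_genes.split(":", 1)
        call_pairs.append((idx, _pair(g5, g3, unordered), row))
    pair_counts: dict = {}
    for _, p, _ in call_pairs:
        pair_counts[p] = pair_counts.get(p, 0) + 1

    potentials = []  # (distance, rank, truth_id, call_idx)
    for _, trow in truth.iterrows():
        tpair = _pair(trow.gene5, trow.gene3, unordered)
        for rank, (cidx, cpair, crow) in enumerate(call_pairs):
            d = _bp_distance(crow, trow)
            if cpair == tpair or d <= radius:
                potentials.append((d, rank, trow.fusion_id, cidx))
    potentials.sort(key=lambda t: (t[0], t[1], t[2]))
    used_truth: set = set()
    used_call: set = set()
    assigned: dict = {}
    for d, rank, tid, cidx in potentials:
        if tid in used_truth or cidx in used_call:
            continue
        used_truth.add(tid)
        used_call.add(cidx)
        assigned[tid] = (cidx, d)
    out = []
    for _, trow in truth.iterrows():
        tpair = _pair(trow.gene5, trow.gene3, unordered)
        if trow.fusion_id in assigned:
            cidx, d = assigned[trow.fusion_id]
            crow = calls.loc[cidx]
            out.append(MatchResult(
                truth_id=trow.fusion_id, call_index=cidx, distance=d,
                exact=(d == 0), classification=crow.classification,
                n_breakpoints=pair_counts.get(tpair, 1)))
        else:
            out.append(MatchResult(trow.fusion_id, None, math.inf, False,
                                   None, 0))
    return out


def matches_to_frame(matches: list[MatchResult], truth: pd.DataFrame
                     ) -> pd.DataFrame:
    df = pd.DataFrame([{
        "fusion_id": m.truth_id, "detected": m.call_index is not None,
        "distance": m.distance, "exact": m.exact,
        "classification": m.classification, "n_breakpoints": m.n_breakpoints,
    } for m in matches])
    return df.merge(truth[["fusion_id", "coverage", "identity"]], on="fusion_id")


def sensitivity_grid(matches: list[MatchResult], truth: pd.DataFrame
                     ) -> tuple[pd.DataFrame, dict]:
    """Detected fraction per (coverage, identity) cell plus overall shares.

    Returns (grid, summary) where summary holds the fraction of detected
    fusions ranked High Confidence, reported with a single breakpoint, and
    with an exact breakpoint.
    """
    df = matches_to_frame(matches, truth)
    grid = (df.pivot_table(index="coverage", columns="identity",
                           values="detected", aggfunc="mean", dropna=False)
            .sort_index().sort_index(axis=1))
    det = df[df.detected]
    summary = {
        "n_truth": int(len(df)),
        "n_detected": int(len(det)),
        "detected_fraction": float(df.detected.mean()) if len(df) else float("nan"),
        "high_confidence_share": (
            float((det.classification == "HighConfidence").mean())
            if len(det) else float("nan")),
        "single_breakpoint_share": (
            float((det.n_breakpoints == 1).mean()) if len(det) else float("nan")),
        "exact_share": float(det.exact.mean()) if len(det) else float("nan"),
    }
    return grid, summary


def support_recovery(matches: list[MatchResult], calls: pd.DataFrame,
                     truth: pd.DataFrame) -> pd.Series:
    """Mean (reported supporting reads) / (simulated coverage) among detected
    fusions, grouped by identity level."""
    truth_idx = truth.set_index("fusion_id")
    rows = []
    for m in matches:
        if m.call_index is None:
            continue
        t = truth_idx.loc[m.truth_id]
        n_reads = int(calls.loc[m.call_index, "spanning_reads"])
        rows.append({"identity": t.identity,
                     "recovery": n_reads / float(t.coverage)})
    if not rows:
        return pd.Series(dtype=float, name="recovery")
    df = pd.DataFrame(rows)
    return df.groupby("identity")["recovery"].mean()


def compare_callsets(set_a: pd.DataFrame, set_b: pd.DataFrame,
                     unordered: bool = True, bp_radius: float = 20.0
                     ) -> pd.DataFrame:
    """Gene-pair level concordance of two call tables, with per-pair
    breakpoint agreement within ``bp_radius``."""
    def index(df):
        out: dict = {}
        for _, row in df.iterrows():
            g5, g3 = row.fusion_genes.split(":", 1)
            out.setdefault(_pair(g5, g3, unordered), []).append(row)
        return out

    ia, ib = index(set_a), index(set_b)
    rows = []
    for pair in sorted({*ia, *ib}, key=str):
        in_a, in_b = pair in ia, pair in ib
        bp_agree = False
        if in_a and in_b:
            for ra in ia[pair]:
                for rb in ib[pair]:
                    if _bp_distance(ra, rb) <= bp_radius:
                        bp_agree = True
        rows.append({"pair": ":".join(sorted(pair) if unordered else pair),
                     "in_a": in_a, "in_b": in_b,
                     "breakpoint_agreement": bp_agree})
    return pd.DataFrame(rows, columns=["pair", "in_a", "in_b",
                                       "breakpoint_agreement"])


def load_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_calls_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
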