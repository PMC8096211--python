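"""Benchmarking of caller output against simulated (or curated) truth.

Calls are matched 1-1 to truth insertions greedily by breakpoint
distance, within a maximum distance (default 50 bp) and — when
family-aware — only if the called transposon belongs to the true
insertion's family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class MatchSpec:
    max_distance: int = 50
    family_aware: bool = True
    accurate_tolerance: int = 5

    def __post_init__(self) -> None:
        if self.accurate_tolerance > self.max_distance:
            raise ValueError("accurate tolerance must not exceed match distance")


@dataclass
class MatchedPair:
    call: object
    truth: object
    distance: int


def _call_family(call, family_of: Mapping[str, str] | None) -> str:
    fam = getattr(call, "family", None) or call.transposon
    if family_of:
        return family_of.get(call.transposon, fam)
    return fam


def match_calls(
    calls: Sequence,
    truth: Sequence,
    spec: MatchSpec | None = None,
    family_of: Mapping[str, str] | None = None,
) -> list[MatchedPair]:
    """Greedy 1-1 matching of calls to truth records by distance.

    Candidate (call, truth) pairs within ``max_distance`` on the same
    chromosome (and compatible family, if family-aware) are sorted by
    distance and assigned first-come.
    """
    spec = spec or MatchSpec()
    edges = []
    for ci, call in enumerate(calls):
        for ti, tr in enumerate(truth):
            if call.chrom != tr.chrom:
                continue
            d = abs(call.breakpoint - tr.pos)
            if d > spec.max_distance:
                continue
            if spec.family_aware:
                t_fam = (
                    family_of.get(tr.transposon, tr.transposon)
                    if family_of
                    else tr.transposon
                )
                if _call_family(call, family_of) != t_fam:
                    continue
            edges.append((d, ci, ti))
    edges.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    out = []
    for d, ci, ti in edges:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        out.append(MatchedPair(calls[ci], truth[ti], d))
    return out


def detection_metrics(
    calls: Sequence,
    truth: Sequence,
    spec: MatchSpec | None = None,
    min_support: int | None = None,
    family_of: Mapping[str, str] | None = None,
) -> tuple[float, float, float]:
    """(sensitivity, precision, F1) of insertion detection."""
    if len(truth) == 0:
        raise ValueError("sensitivity undefined for empty truth")
    if min_support is not None:
        calls = [c for c in calls if c.n_support >= min_support]
    matches = match_calls(calls, truth, spec, family_of)
    tp = len(matches)
    sensitivity = tp / len(truth)
    precision = tp / len(calls) if calls else 0.0
    f1 = (
        2 * sensitivity * precision / (sensitivity + precision)
        if (sensitivity + precision) > 0
        else 0.0
    )
    return sensitivity, precision, f1


def frequency_error(matches: Sequence[MatchedPair]) -> float:
    """Mean |estimated - simulated| insertion frequency over matches."""
    if not matches:
        raise ValueError("no matched pairs")
    return float(
        np.mean([abs(m.call.frequency - m.truth.frequency) for m in matches])
    )


def breakpoint_distance(
    matches: Sequence[MatchedPair], accurate_tolerance: int = 5
) -> tuple[float, float]:
    """(mean breakpoint distance in bp, fraction within tolerance)."""
    if not matches:
        raise ValueError("no matched pairs")
    d = np.array([m.distance for m in matches], dtype=float)
    return float(d.mean()), float(np.mean(d <= accurate_tolerance))


def te_end_distance(matches: Sequence[MatchedPair]) -> float:
    """Mean distance between predicted and true transposon ends, averaged
    over both ends of each matched insertion."""
    if not matches:
        raise ValueError("no matched pairs")
    dists = []
    for m in matches:
        dists.append(abs(m.call.te_start - m.truth.te_start))
        dists.append(abs(m.call.te_end - m.truth.te_end))
    return float(np.mean(dists))


def de_novo_ssr(
    estimates: Mapping[str, float], truth: Mapping[str, float]
) -> float:
    """Sum of squared residuals between estimated and simulated per-genome
    de novo insertion numbers over *all* families, zero-truth included."""
    families = set(estimates) | set(truth)
    return float(
        sum(
            (estimates.get(f, 0.0) - truth.get(f, 0.0)) ** 2
            for f in families
        )
    )


def de_novo_correlation(
    estimates: Mapping[str, float], truth: Mapping[str, float]
) -> float:
    """Pearson correlation across families (zero-truth families included)."""
    families = sorted(set(estimates) | set(truth))
    x = np.array([truth.get(f, 0.0) for f in families])
    y = np.array([estimates.get(f, 0.0) for f in families])
    r, _ = stats.pearsonr(x, y)
    return float(r)


# ---------------------------------------------------------------------------
# End bias / terminal composition QC
# ---------------------------------------------------------------------------

def cg_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("C") + seq.count("G")) / len(seq)


@dataclass
class EndBiasRecord:
    family: str
    n_5p: int
    n_3p: int
    bias: float  # log2((n5+1)/(n3+1))
    cg_5p: float  # CG of the first terminal_nt of the consensus
    cg_3p: float


def end_bias_and_cg(
    calls: Sequence,
    library,
    terminal_nt: int = 40,
) -> dict[str, EndBiasRecord]:
    """Supporting-read end bias per family vs terminal CG content.

    Bias is log2((n5'+1)/(n3'+1)) summed over that family's calls; the CG
    content is measured on the first and last ``terminal_nt`` of the
    (lexicographically first) consensus of the family.
    """
    per_family: dict[str, list] = {}
    for call in calls:
        per_family.setdefault(call.family, []).append(call)
    out = {}
    for family, group in sorted(per_family.items()):
        n5 = sum(c.n_support_5p for c in group)
        n3 = sum(c.n_support_3p for c in group)
        member = library.members(family)[0]
        seq = library.entries[member]
        out[family] = EndBiasRecord(
            family=family,
            n_5p=n5,
            n_3p=n3,
            bias=float(np.log2((n5 + 1) / (n3 + 1))),
            cg_5p=cg_content(seq[:terminal_nt]),
            cg_3p=cg_content(seq[-terminal_nt:]),
        )
    return out
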