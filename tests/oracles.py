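"""Independent brute-force oracles used to cross-check the package.

Everything here is written against the definitions directly, with different
primitives than the implementation (position sets, explicit pair lists,
exhaustive enumeration, closed-form statistics), and must stay independent
of the code paths it checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

# --------------------------------------------------------------------------
# class codes, per definition, over all (candidate, reference) pairs


def _exon_positions(t) -> Set[Tuple[str, int]]:
    out = set()
    for e in t.exons:
        out.update((e.chrom, p) for p in range(e.start, e.end))
    return out


def brute_force_class_code(cand, refs) -> str:
    same_chrom = [r for r in refs if r.chrom == cand.chrom]
    if refs and not same_chrom:
        return "u"

    def is_equal(r) -> bool:
        if r.strand != cand.strand:
            return False
        if len(cand.exons) == 1 and len(r.exons) == 1:
            return (cand.exons[0].start, cand.exons[0].end) == (
                r.exons[0].start,
                r.exons[0].end,
            )
        if len(cand.exons) > 1 and len(r.exons) > 1:
            return tuple(cand.introns) == tuple(r.introns)
        return False

    if any(is_equal(r) for r in same_chrom):
        return "="
    if any(
        r.strand == cand.strand and set(cand.introns) & set(r.introns)
        for r in same_chrom
    ):
        return "j"
    cand_pos = _exon_positions(cand)
    if any(
        r.strand == cand.strand and cand_pos & _exon_positions(r)
        for r in same_chrom
    ):
        return "o"
    if any(
        lo <= cand.start and cand.end <= hi
        for r in same_chrom
        for (lo, hi) in r.introns
    ):
        return "i"
    if any(
        r.strand != cand.strand and cand_pos & _exon_positions(r)
        for r in same_chrom
    ):
        return "x"
    return "u"


# --------------------------------------------------------------------------
# exhaustive ORF scan: every ATG walked to its first in-frame stop

_STOPS = {"TAA", "TAG", "TGA"}


def exhaustive_longest_orf(seq: str) -> int:
    s = seq.upper().replace("U", "T")
    best = 0
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(s):
            if s[j : j + 3] in _STOPS:
                best = max(best, j + 3 - i)
                break
            j += 3
    return best


# --------------------------------------------------------------------------
# duplex pairing, literal

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def _state(mir_base: str, target_base: str) -> str:
    if (mir_base, target_base) in _WC:
        return "WC"
    if (mir_base, target_base) in _GU:
        return "GU"
    return "MM"


def literal_cleavage_penalty(mirna: str, window: str) -> float:
    """Direct per-position summation of the cleavage scoring scheme."""
    mir = mirna.upper().replace("T", "U")
    win = window.upper().replace("T", "U")
    m = len(mir)
    assert len(win) == m
    penalty = 0.0
    for p in range(1, m + 1):
        st = _state(mir[p - 1], win[m - p])
        w = {"WC": 0.0, "GU": 0.5, "MM": 1.0}[st]
        penalty += w * (2.0 if 2 <= p <= 13 else 1.0)
    return penalty


def literal_cleavage_scan(
    mirna: str, target: str, cutoff: float = 4.0
) -> Set[int]:
    mir = mirna.upper().replace("T", "U")
    tgt = target.upper().replace("T", "U")
    m = len(mir)
    return {
        s
        for s in range(len(tgt) - m + 1)
        if literal_cleavage_penalty(mir, tgt[s : s + m]) <= cutoff
    }


def enumerate_etm_sites(
    mirna: str,
    lncrna: str,
    bulge_range: Tuple[int, int] = (3, 5),
    max_weighted: float = 4.0,
    max_run: int = 2,
    gu_weight: float = 0.5,
    gu_counts: bool = True,
) -> Set[Tuple[int, int]]:
    """Literal enumeration of every (start, bulge) against the three rules.

    Builds the explicit (miRNA position, target index) pair list for each
    placement and applies the rules with no shortcuts. Returns the set of
    accepted (start, bulge_len).
    """
    mir = mirna.upper().replace("T", "U")
    lnc = lncrna.upper().replace("T", "U")
    m = len(mir)
    accepted = set()
    for b in range(bulge_range[0], bulge_range[1] + 1):
        for s in range(len(lnc) - (m + b) + 1):
            pairs: List[Tuple[int, int]] = []
            for k in range(m - 10):  # miRNA positions m .. 11
                pairs.append((m - k, s + k))
            for k in range(10):  # miRNA positions 10 .. 1
                pairs.append((10 - k, s + (m - 10) + b + k))
            state: Dict[int, str] = {
                p: _state(mir[p - 1], lnc[idx]) for p, idx in pairs
            }
            rule1 = (
                state[10] == "WC"
                and state[11] == "WC"
                and bulge_range[0] <= b <= bulge_range[1]
                and 3 <= b <= 5
            )
            weighted = 0.0
            for p in range(1, m + 1):
                if p in (10, 11):
                    continue
                if state[p] == "MM":
                    weighted += 1.0
                elif state[p] == "GU" and gu_counts:
                    weighted += gu_weight
            run = 0
            worst = 0
            for p in range(1, m + 1):
                if p in (10, 11):
                    run = 0
                elif state[p] == "MM":
                    run += 1
                    worst = max(worst, run)
                elif state[p] == "WC":
                    run = 0
            rule2 = weighted <= max_weighted and worst <= max_run
            if rule1 and rule2:
                accepted.add((s, b))
    return accepted


# --------------------------------------------------------------------------
# Welch t-test from the closed-form statistic


def welch_p_value(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


# --------------------------------------------------------------------------
# random transcript models for classification fuzzing


def random_transcript(rng: np.random.Generator, tid: str, space: int = 3000):
    from cerna.models import GenomicInterval, TranscriptModel

    chrom = f"chr{rng.integers(1, 3)}"
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(space, size=2 * n_exons, replace=False).tolist())
    exons = []
    for i in range(n_exons):
        lo, hi = cuts[2 * i], cuts[2 * i + 1]
        if hi == lo:
            hi += 1
        exons.append(GenomicInterval(chrom, lo, hi, strand))
    merged = [exons[0]]
    for e in exons[1:]:
        if e.start <= merged[-1].end:  # keep a real intron between exons
            continue
        merged.append(e)
    return TranscriptModel(id=tid, exons=tuple(merged))
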