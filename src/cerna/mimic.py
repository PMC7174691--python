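"""The duplex rule engine: miRNA cleavage-site scoring and endogenous
target-mimic (eTM) site detection.

Both modes classify antiparallel base pairs as Watson-Crick (WC), G:U wobble
(GU) or MISMATCH and work on miRNA positions numbered 1..m from the 5' end.

Cleavage mode scores an ungapped window on the target: each position adds
``w(state) * region`` to a penalty, with ``w(MISMATCH)=1``, ``w(GU)=0.5``,
``w(WC)=0`` and region multiplier 2 inside the functionally critical miRNA
positions 2-13; a window is an accepted cleavage site iff the penalty does
not exceed the cutoff (default 4.0).

Mimic mode implements the strict plant eTM geometry: the target (lncRNA)
site pairs the miRNA 3' arm (positions m..11), presents an unpaired bulge of
3-5 target nucleotides strictly between the bases pairing miRNA positions 10
and 11, then pairs the 5' arm (positions 10..1). A site is accepted iff

1. miRNA positions 10 and 11 are both WC-paired and the bulge length is
   within the allowed range;
2. the weighted mismatch total over the non-central positions (GU = 0.5,
   MISMATCH = 1) is at most 4, with no run of more than 2 consecutive
   mismatches (a GU pair neither adds to nor resets a run);
3. no gaps or protrusions occur anywhere except the central bulge (which
   the ungapped-arm alignment model enforces structurally).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .seq import to_rna, validate_nt


class PairState(enum.Enum):
    WC = "WC"
    GU = "GU"
    MISMATCH = "MISMATCH"


_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

#: full 16-entry lookup, miRNA base x target base
PAIR_TABLE: Dict[Tuple[str, str], PairState] = {
    (a, b): (
        PairState.WC
        if (a, b) in _WC_PAIRS
        else PairState.GU
        if (a, b) in _GU_PAIRS
        else PairState.MISMATCH
    )
    for a in "ACGU"
    for b in "ACGU"
}


def pair_state(mirna_base: str, target_base: str) -> PairState:
    """Classify one antiparallel base pair (RNA alphabet)."""
    key = (mirna_base.upper(), target_base.upper())
    if key not in PAIR_TABLE:
        raise ValueError(f"invalid base pair {mirna_base!r}:{target_base!r}")
    return PAIR_TABLE[key]


@dataclass(frozen=True)
class CleavageParams:
    """Scoring scheme for miRNA-directed cleavage sites."""

    cutoff: float = 4.0
    mismatch_weight: float = 1.0
    gu_weight: float = 0.5
    core_start: int = 2  # 1-based miRNA positions with doubled weight
    core_end: int = 13
    core_multiplier: float = 2.0


@dataclass(frozen=True)
class MimicRuleParams:
    """Parameters of the three eTM acceptance rules."""

    central_positions: Tuple[int, int] = (10, 11)
    bulge_min: int = 3
    bulge_max: int = 5
    max_noncentral_mismatches: float = 4.0
    max_consecutive_mismatches: int = 2
    gu_counts_as_mismatch: bool = True
    gu_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.bulge_min > self.bulge_max:
            raise ValueError("empty bulge range")
        if self.bulge_min < 0 or self.bulge_max > 10:
            raise ValueError("bulge range must lie within [0, 10]")
        if self.max_noncentral_mismatches < 0:
            raise ValueError("mismatch budget must be >= 0")
        if self.max_consecutive_mismatches < 0:
            raise ValueError("consecutive-mismatch limit must be >= 0")


@dataclass
class RnaDuplex:
    """One scored antiparallel miRNA:site alignment.

    ``states[k]`` is the pair state of miRNA position ``k+1``. ``start`` /
    ``end`` delimit the site on the target, 0-based half-open.
    """

    mirna_id: str
    target_id: str
    start: int
    end: int
    mode: str  # "cleavage" | "mimic"
    states: Tuple[PairState, ...]
    penalty: float = 0.0
    bulge_len: int = 0
    weighted_mismatches: float = 0.0
    max_consecutive: int = 0
    accepted: bool = False


@dataclass
class EtmSite:
    """A mimic-mode duplex with the per-rule verdicts."""

    duplex: RnaDuplex
    rule1_central_bulge: bool
    rule2_mismatch_budget: bool
    rule3_no_protrusion: bool

    @property
    def accepted(self) -> bool:
        return (
            self.rule1_central_bulge
            and self.rule2_mismatch_budget
            and self.rule3_no_protrusion
        )

    @property
    def failing_rule(self) -> str:
        if not self.rule1_central_bulge:
            return "central_bulge"
        if not self.rule2_mismatch_budget:
            return "mismatch_budget"
        if not self.rule3_no_protrusion:
            return "protrusion"
        return ""


def _norm(seq: str, what: str) -> str:
    s = to_rna(seq)
    try:
        validate_nt(s, "ACGU")
    except ValueError as exc:
        raise ValueError(f"{what}: {exc}") from exc
    return s


def score_cleavage_site(
    mirna: str,
    window: str,
    params: CleavageParams | None = None,
    mirna_id: str = "",
    target_id: str = "",
    start: int = 0,
) -> RnaDuplex:
    """Score one ungapped window (target subsequence, 5'->3') of miRNA length.

    The alignment is antiparallel: miRNA position p pairs window base
    ``window[m - p]``, so a perfect site is the reverse complement of the
    miRNA.
    """
    params = params or CleavageParams()
    mir = _norm(mirna, "mirna")
    win = _norm(window, "window")
    m = len(mir)
    if len(win) != m:
        raise ValueError(
            f"window length {len(win)} != miRNA length {m} (ungapped mode)"
        )
    states = []
    penalty = 0.0
    for p in range(1, m + 1):
        st = PAIR_TABLE[(mir[p - 1], win[m - p])]
        w = (
            0.0
            if st is PairState.WC
            else params.gu_weight
            if st is PairState.GU
            else params.mismatch_weight
        )
        region = (
            params.core_multiplier
            if params.core_start <= p <= params.core_end
            else 1.0
        )
        penalty += w * region
        states.append(st)
    return RnaDuplex(
        mirna_id=mirna_id,
        target_id=target_id,
        start=start,
        end=start + m,
        mode="cleavage",
        states=tuple(states),
        penalty=penalty,
        accepted=penalty <= params.cutoff,
    )


def scan_cleavage_sites(
    mirna: str,
    target: str,
    params: CleavageParams | None = None,
    mirna_id: str = "",
    target_id: str = "",
) -> List[RnaDuplex]:
    """All accepted cleavage sites on ``target`` (every window scored)."""
    params = params or CleavageParams()
    mir = _norm(mirna, "mirna")
    tgt = _norm(target, "target")
    m = len(mir)
    hits = []
    # precompute per-position region multipliers once
    mult = [
        params.core_multiplier
        if params.core_start <= p <= params.core_end
        else 1.0
        for p in range(1, m + 1)
    ]
    for s in range(len(tgt) - m + 1):
        penalty = 0.0
        for p in range(1, m + 1):
            st = PAIR_TABLE[(mir[p - 1], tgt[s + m - p])]
            if st is PairState.WC:
                continue
            w = (
                params.gu_weight
                if st is PairState.GU
                else params.mismatch_weight
            )
            penalty += w * mult[p - 1]
            if penalty > params.cutoff:
                break
        if penalty <= params.cutoff:
            hits.append(
                score_cleavage_site(
                    mir, tgt[s : s + m], params, mirna_id, target_id, s
                )
            )
    return hits


def _mimic_states(
    mir: str, lnc: str, start: int, bulge_len: int
) -> Tuple[PairState, ...]:
    """Pair states of the mimic alignment at (start, bulge_len).

    Site layout on the target, 5'->3': bases pairing miRNA positions m..11,
    then ``bulge_len`` unpaired bases, then bases pairing positions 10..1.
    """
    m = len(mir)
    states: List[Optional[PairState]] = [None] * m
    for k in range(m - 10):  # miRNA positions m down to 11
        states[m - 1 - k] = PAIR_TABLE[(mir[m - 1 - k], lnc[start + k])]
    off = start + (m - 10) + bulge_len
    for k in range(10):  # miRNA positions 10 down to 1
        states[9 - k] = PAIR_TABLE[(mir[9 - k], lnc[off + k])]
    return tuple(states)  # type: ignore[arg-type]


def _mismatch_stats(
    states: Sequence[PairState], params: MimicRuleParams
) -> Tuple[float, int]:
    """(weighted non-central mismatches, longest mismatch run).

    The run counter ignores central positions (they are a separate region),
    increments on MISMATCH, resets on WC and is left unchanged by GU.
    """
    central = set(params.central_positions)
    weighted = 0.0
    run = 0
    max_run = 0
    for p, st in enumerate(states, start=1):
        if p in central:
            run = 0
            continue
        if st is PairState.MISMATCH:
            weighted += 1.0
            run += 1
            max_run = max(max_run, run)
        elif st is PairState.GU:
            if params.gu_counts_as_mismatch:
                weighted += params.gu_weight
        else:
            run = 0
    return weighted, max_run


def evaluate_etm_site(
    mirna: str,
    lncrna: str,
    start: int,
    bulge_len: int,
    params: MimicRuleParams | None = None,
    mirna_id: str = "",
    lncrna_id: str = "",
) -> EtmSite:
    """Evaluate the three mimic rules at one (start, bulge_len) placement.

    Rule 3 concerns non-central gaps/protrusions; the alignment model used
    here is structurally ungapped outside the central bulge, so it always
    passes for an alignment that fits — a planted protrusion simply shifts
    the arms out of register and fails rules 1-2 instead.
    """
    params = params or MimicRuleParams()
    mir = _norm(mirna, "mirna")
    lnc = _norm(lncrna, "lncrna")
    m = len(mir)
    if m < 15:
        raise ValueError(
            f"miRNA of {m} nt is too short: central positions "
            f"{params.central_positions} require >= 15 nt"
        )
    site_len = m + bulge_len
    if start < 0 or start + site_len > len(lnc):
        raise ValueError("site does not fit inside the target sequence")

    states = _mimic_states(mir, lnc, start, bulge_len)
    p10, p11 = params.central_positions
    rule1 = (
        states[p10 - 1] is PairState.WC
        and states[p11 - 1] is PairState.WC
        and params.bulge_min <= bulge_len <= params.bulge_max
    )
    weighted, max_run = _mismatch_stats(states, params)
    rule2 = (
        weighted <= params.max_noncentral_mismatches
        and max_run <= params.max_consecutive_mismatches
    )
    rule3 = True
    duplex = RnaDuplex(
        mirna_id=mirna_id,
        target_id=lncrna_id,
        start=start,
        end=start + site_len,
        mode="mimic",
        states=states,
        bulge_len=bulge_len,
        weighted_mismatches=weighted,
        max_consecutive=max_run,
        accepted=rule1 and rule2 and rule3,
    )
    return EtmSite(duplex, rule1, rule2, rule3)


def find_etm_sites(
    mirna: str,
    lncrna: str,
    params: MimicRuleParams | None = None,
    mirna_id: str = "",
    lncrna_id: str = "",
) -> List[EtmSite]:
    """All accepted eTM sites, exhaustively over starts and bulge lengths.

    Overlapping accepted sites are all reported; no best-site reduction.
    """
    params = params or MimicRuleParams()
    mir = _norm(mirna, "mirna")
    lnc = _norm(lncrna, "lncrna")
    m = len(mir)
    if m < 15:
        raise ValueError(
            f"miRNA of {m} nt is too short: central positions "
            f"{params.central_positions} require >= 15 nt"
        )
    hits = []
    for bulge in range(params.bulge_min, params.bulge_max + 1):
        site_len = m + bulge
        for s in range(len(lnc) - site_len + 1):
            # cheap central-pair gate before the full evaluation
            if PAIR_TABLE[(mir[10], lnc[s + m - 11])] is not PairState.WC:
                continue
            if (
                PAIR_TABLE[(mir[9], lnc[s + m - 10 + bulge])]
                is not PairState.WC
            ):
                continue
            site = evaluate_etm_site(
                mir, lnc, s, bulge, params, mirna_id, lncrna_id
            )
            if site.accepted:
                hits.append(site)
    return hits


def predict_etm_sites(
    mirnas: Mapping[str, str],
    lncrnas: Mapping[str, str],
    params: MimicRuleParams | None = None,
) -> pd.DataFrame:
    """Scan every miRNA against every lncRNA; tabulate accepted sites."""
    rows = []
    for mid in sorted(mirnas):
        for lid in sorted(lncrnas):
            for site in find_etm_sites(
                mirnas[mid], lncrnas[lid], params, mid, lid
            ):
                d = site.duplex
                rows.append(
                    {
                        "mirna": mid,
                        "target": lid,
                        "start": d.start,
                        "end": d.end,
                        "mode": "mimic",
                        "bulge_len": d.bulge_len,
                        "weighted_mismatches": d.weighted_mismatches,
                        "penalty": float("nan"),
                        "accepted": True,
                        "failing_rule": "",
                    }
                )
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def predict_cleavage_sites(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    params: CleavageParams | None = None,
) -> pd.DataFrame:
    """Scan every miRNA against every transcript; tabulate accepted sites."""
    rows = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            for d in scan_cleavage_sites(
                mirnas[mid], transcripts[tid], params, mid, tid
            ):
                rows.append(
                    {
                        "mirna": mid,
                        "target": tid,
                        "start": d.start,
                        "end": d.end,
                        "mode": "cleavage",
                        "bulge_len": 0,
                        "weighted_mismatches": float("nan"),
                        "penalty": d.penalty,
                        "accepted": True,
                        "failing_rule": "",
                    }
                )
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


_SITE_COLUMNS = [
    "mirna",
    "target",
    "start",
    "end",
    "mode",
    "bulge_len",
    "weighted_mismatches",
    "penalty",
    "accepted",
    "failing_rule",
]
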