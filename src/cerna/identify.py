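"""lncRNA identification: class-code assignment and the filtering cascade.

Candidate transcripts (assembled transfrags) are classified against a
reference annotation with the gffcompare-style class codes

* ``=`` exact intron-chain match with a same-strand reference,
* ``j`` at least one internal splice junction shared with a same-strand
  reference,
* ``o`` same-strand exonic overlap without a shared junction,
* ``i`` transfrag falling entirely within a reference intron,
* ``x`` exonic overlap with a reference on the opposite strand,
* ``u`` unknown, intergenic transcript,

and lncRNAs are the candidates with code in {i, j, o, u, x} that survive a
length filter (>= 200 nt), a read-support filter (>= 3 reads) and a
coding-potential filter.

Coding potential is scored with a transparent open-reading-frame rule: a
transcript is called coding iff its longest forward-frame ATG-to-stop ORF is
at least 300 nt long or covers at least half the transcript. This replaces
external SVM/alignment classifiers with a deterministic, testable surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .models import TranscriptModel
from .seq import validate_nt

logger = logging.getLogger(__name__)

#: class codes in precedence order; a candidate receives the first that applies
CLASS_CODES = ("=", "j", "o", "i", "x", "u")

#: codes eligible to become lncRNAs
LNCRNA_CODES = frozenset("ijoux")

_STOPS = frozenset({"TAA", "TAG", "TGA"})


def _chain_equal(candidate: TranscriptModel, ref: TranscriptModel) -> bool:
    """Exact structural match.

    Multi-exon: identical intron chain (terminal exon ends may differ).
    Single-exon transcripts carry no junctions, so the match degenerates to
    exact exon coordinates against a single-exon reference.
    """
    if candidate.strand != ref.strand or candidate.chrom != ref.chrom:
        return False
    if len(candidate.exons) == 1 and len(ref.exons) == 1:
        return (
            candidate.exons[0].start == ref.exons[0].start
            and candidate.exons[0].end == ref.exons[0].end
        )
    if len(candidate.exons) == 1 or len(ref.exons) == 1:
        return False
    return candidate.introns == ref.introns


def _exonic_overlap(candidate: TranscriptModel, ref: TranscriptModel) -> bool:
    if candidate.chrom != ref.chrom:
        return False
    return any(
        ce.start < re.end and re.start < ce.end
        for ce in candidate.exons
        for re in ref.exons
    )


def assign_class_code(
    candidate: TranscriptModel,
    annotation: Sequence[TranscriptModel],
) -> str:
    """Assign exactly one class code to ``candidate``.

    Precedence is ``= > j > o > i > x > u``; each code is tested against the
    whole annotation before falling through, so annotation order never
    matters. Candidates on a chromosome absent from the annotation are
    intergenic by definition and come back as ``u`` (with a logged warning).
    """
    refs = [r for r in annotation if r.chrom == candidate.chrom]
    if annotation and not refs:
        logger.warning(
            "candidate %s is on chromosome %r absent from the annotation; "
            "treating as intergenic (u)",
            candidate.id,
            candidate.chrom,
        )
        return "u"

    if any(_chain_equal(candidate, r) for r in refs):
        return "="

    cand_introns = set(candidate.introns)
    if cand_introns and any(
        r.strand == candidate.strand and cand_introns & set(r.introns)
        for r in refs
    ):
        return "j"

    if any(
        r.strand == candidate.strand and _exonic_overlap(candidate, r)
        for r in refs
    ):
        return "o"

    span = (candidate.start, candidate.end)
    if any(
        i_start <= span[0] and span[1] <= i_end
        for r in refs
        for (i_start, i_end) in r.introns
    ):
        return "i"

    if any(
        r.strand != candidate.strand and _exonic_overlap(candidate, r)
        for r in refs
    ):
        return "x"

    return "u"


@dataclass(frozen=True)
class CodingPotential:
    longest_orf_nt: int
    score: float
    is_coding: bool


def coding_potential_score(
    sequence: str,
    orf_min_nt: int = 300,
    orf_max_fraction: float = 0.5,
) -> CodingPotential:
    """ORF-based coding-potential surrogate.

    ``longest_orf_nt`` is the length (including the stop codon) of the
    longest ATG-to-in-frame-stop ORF over the three forward frames; an open
    reading without a stop codon does not count. ``score`` is that length
    divided by the transcript length. Coding iff
    ``longest_orf_nt >= orf_min_nt`` or ``score >= orf_max_fraction``.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    validate_nt(sequence, "ACGTU")
    s = sequence.upper().replace("U", "T")

    longest = 0
    for frame in range(3):
        open_start = None  # earliest unclosed ATG in this frame
        for k in range(frame, len(s) - 2, 3):
            codon = s[k : k + 3]
            if codon in _STOPS:
                if open_start is not None:
                    longest = max(longest, k + 3 - open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = k
    score = longest / len(s)
    is_coding = longest >= orf_min_nt or score >= orf_max_fraction
    return CodingPotential(longest, score, is_coding)


@dataclass
class IdentifyParams:
    """Thresholds of the identification cascade (defaults as published)."""

    min_length: int = 200
    min_reads: int = 3
    orf_min_nt: int = 300
    orf_max_fraction: float = 0.5


@dataclass
class FilterReport:
    """Per-stage accounting: retained + rejected == input, always."""

    stage: str
    input_count: int
    retained_count: int
    rejected: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained_count + len(self.rejected) != self.input_count:
            raise ValueError(
                f"stage {self.stage!r}: retained {self.retained_count} + "
                f"rejected {len(self.rejected)} != input {self.input_count}"
            )


#: fixed cascade order
CASCADE_STAGES = ("known_mrna", "length", "read_support", "coding_potential")


def identify_lncrnas(
    candidates: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    params: IdentifyParams | None = None,
) -> Tuple[List[TranscriptModel], List[FilterReport], pd.DataFrame]:
    """Run the full identification cascade.

    Returns the retained lncRNA transcripts, one :class:`FilterReport` per
    stage (in cascade order), and a per-candidate table with the class code,
    ORF statistics and the stage of rejection (empty string if retained).
    An empty candidate set yields empty outputs with zero-count reports.
    """
    params = params or IdentifyParams()
    reports: List[FilterReport] = []
    rows = []

    codes = {c.id: assign_class_code(c, annotation) for c in candidates}
    orf = {
        c.id: coding_potential_score(
            c.sequence, params.orf_min_nt, params.orf_max_fraction
        )
        if c.sequence is not None
        else None
        for c in candidates
    }

    surviving = list(candidates)
    rejection_stage: Dict[str, str] = {}

    def run_stage(stage: str, keep, reason) -> None:
        nonlocal surviving
        kept, rejected = [], {}
        for c in surviving:
            if keep(c):
                kept.append(c)
            else:
                rejected[c.id] = reason(c)
                rejection_stage[c.id] = stage
        reports.append(
            FilterReport(stage, len(surviving), len(kept), rejected)
        )
        surviving = kept

    run_stage(
        "known_mrna",
        lambda c: codes[c.id] in LNCRNA_CODES,
        lambda c: f"class code {codes[c.id]!r} marks a known mRNA structure",
    )
    run_stage(
        "length",
        lambda c: c.length >= params.min_length,
        lambda c: f"length {c.length} nt < {params.min_length} nt",
    )
    run_stage(
        "read_support",
        lambda c: c.read_support >= params.min_reads,
        lambda c: f"read support {c.read_support} < {params.min_reads}",
    )

    def noncoding(c: TranscriptModel) -> bool:
        cp = orf[c.id]
        if cp is None:
            raise ValueError(
                f"candidate {c.id!r} has no sequence; coding-potential "
                "filtering requires sequences"
            )
        return not cp.is_coding

    run_stage(
        "coding_potential",
        noncoding,
        lambda c: (
            f"called coding (longest ORF {orf[c.id].longest_orf_nt} nt, "
            f"score {orf[c.id].score:.3f})"
        ),
    )

    for c in candidates:
        cp = orf[c.id]
        rows.append(
            {
                "transcript_id": c.id,
                "class_code": codes[c.id],
                "length": c.length,
                "read_support": c.read_support,
                "orf_nt": cp.longest_orf_nt if cp else pd.NA,
                "orf_score": cp.score if cp else pd.NA,
                "retained": c.id not in rejection_stage,
                "rejection_stage": rejection_stage.get(c.id, ""),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "class_code",
            "length",
            "read_support",
            "orf_nt",
            "orf_score",
            "retained",
            "rejection_stage",
        ],
    )
    return surviving, reports, table
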