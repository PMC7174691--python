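"""Synthetic data with known ground truth for the whole inference chain.

The generator emulates the study design the pipeline expects: a reference
annotation of multi-exon mRNAs on a small multi-chromosome genome, candidate
transfrags engineered to receive each class code (i, j, o, u, x) plus
exact-match decoys, mature miRNAs, lncRNAs carrying planted endogenous
target-mimic (eTM) sites that obey or violate the mimic rules, planted
miRNA cleavage sites on reference mRNAs, and a genotype x condition x
replicate count matrix with planted log2 fold-changes.

Counts are drawn from a negative binomial (mean proportional to transcript
length x baseline expression x 2^(log2fc x salt indicator), overdispersion
``dispersion``), the standard overdispersed model for bulk RNA-seq counts.

Everything is a pure function of :class:`SimulationConfig`; a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diffexpr import CONDITIONS, GENOTYPES, ExpressionTable, SampleDesign
from .identify import coding_potential_score
from .models import GenomicInterval, TranscriptModel
from .seq import revcomp_dna, random_dna

#: violation classes planted on dedicated lncRNAs (one each)
VIOLATION_CLASSES = (
    "bulge_short",
    "bulge_long",
    "mismatch_budget",
    "consecutive_mismatches",
    "protrusion",
)

_SLOT = 4000  # genomic slot per reference gene
_LNC_SLOT = 1500
_LNC_LEN = 600


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    n_ref_mrna: int = 12
    n_candidates_per_class: int = 2  # per lncRNA-eligible code (i, j, o, u, x)
    n_decoys: int = 2  # exact-match ("=") decoy transfrags
    n_mirna: int = 5
    mirna_length: int = 21
    n_lnc: int = 4  # lncRNAs carrying rule-compliant planted eTM sites
    include_violations: bool = True  # one extra lncRNA per violation class
    replicates: int = 3
    planted_log2fc: float = 2.0
    dispersion: float = 0.03  # NB overdispersion: var = mu + dispersion*mu^2
    mean_expression: float = 50.0  # nominal baseline FPKM
    expression_log2_sd: float = 0.5  # spread of baselines around the mean
    library_size: int = 2_000_000  # nominal fragments per sample
    bulge_length_range: Tuple[int, int] = (3, 5)
    planted_mismatch_counts: Tuple[int, ...] = (0, 1, 2)
    candidate_read_support: int = 5

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.n_ref_mrna < 1:
            raise ValueError("need at least one reference mRNA")
        needed = 5 * self.n_candidates_per_class + self.n_decoys
        if self.n_ref_mrna < max(needed, 1):
            raise ValueError(
                f"n_ref_mrna={self.n_ref_mrna} too small: each candidate "
                f"needs its own reference gene ({needed} required)"
            )
        if self.n_candidates_per_class < 0 or self.n_decoys < 0:
            raise ValueError("candidate counts must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.mirna_length < 15:
            raise ValueError("miRNA length must be >= 15 nt")
        lo, hi = self.bulge_length_range
        if not (0 <= lo <= hi <= 10):
            raise ValueError("bulge_length_range must lie within [0, 10]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mean_expression <= 0:
            raise ValueError("mean_expression must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_mirna < 1:
            raise ValueError("need at least one miRNA")
        for k in self.planted_mismatch_counts:
            if not (0 <= k <= 4):
                raise ValueError(
                    "planted mismatch counts for compliant sites must be 0-4"
                )


@dataclass
class PlantedEtm:
    lncrna: str
    mirna: str
    start: int
    end: int
    bulge_len: int
    mismatch_positions: Tuple[int, ...]
    rule_compliant: bool
    violation: Optional[str] = None


@dataclass
class PlantedCleavage:
    mrna: str
    mirna: str
    start: int  # spliced coordinate on the mRNA
    penalty: float
    accepted_expected: bool


@dataclass
class TruthSet:
    class_code_truth: Dict[str, str] = field(default_factory=dict)
    planted_etm_sites: List[PlantedEtm] = field(default_factory=list)
    planted_cleavage_sites: List[PlantedCleavage] = field(default_factory=list)
    planted_de: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    reference: List[TranscriptModel]
    candidates: List[TranscriptModel]  # class cohort + decoys
    lncrnas: List[TranscriptModel]  # eTM carriers (+ violation carriers)
    mirnas: Dict[str, str]  # id -> DNA sequence
    truth: TruthSet
    expression: ExpressionTable

    @property
    def transcripts(self) -> List[TranscriptModel]:
        return [*self.reference, *self.candidates, *self.lncrnas]

    @property
    def sequences(self) -> Dict[str, str]:
        return {t.id: t.sequence for t in self.transcripts}


def _no_three_consecutive(positions: Sequence[int]) -> bool:
    s = set(positions)
    return not any(p + 1 in s and p + 2 in s for p in s)


_NON_PAIRING = {  # DNA bases that neither WC- nor wobble-pair the miRNA base
    "A": "ACG",
    "C": "ACT",
    "G": "AG",
    "T": "CT",
}


def plant_mimic_site(
    lncrna_seq: str,
    mirna_seq: str,
    position: int,
    bulge_len: int,
    mismatches: Sequence[int] = (),
    rng: Optional[np.random.Generator] = None,
    occupied: Sequence[Tuple[int, int]] = (),
    protrusion_at: Optional[int] = None,
) -> Tuple[str, PlantedEtm]:
    """Overwrite a mimic site into ``lncrna_seq`` (DNA alphabet).

    The site is the reverse complement of the miRNA with ``bulge_len``
    random nucleotides inserted between the bases pairing miRNA positions 10
    and 11; the miRNA positions listed in ``mismatches`` (1-based,
    non-central) are mutated to a base that neither Watson-Crick- nor
    wobble-pairs the miRNA, so planted mismatch counts are unambiguous.
    ``protrusion_at`` additionally inserts one extra nucleotide after the
    site base pairing that (non-central) miRNA position, modelling a
    forbidden non-central protrusion.

    The returned record carries ``rule_compliant`` =
    (3 <= bulge_len <= 5) and |mismatches| <= 4 and no three
    integer-consecutive mismatch positions and no protrusion.
    Overlap with ``occupied`` intervals is rejected with a diagnostic.
    """
    rng = rng or np.random.default_rng(0)
    mir = mirna_seq.upper().replace("U", "T")
    m = len(mir)
    if m < 15:
        raise ValueError("miRNA must be >= 15 nt")
    if bulge_len < 0:
        raise ValueError("bulge length must be >= 0")
    for p in mismatches:
        if not (1 <= p <= m) or p in (10, 11):
            raise ValueError(
                f"mismatch position {p} invalid: must be non-central "
                f"(1-9, 12-{m})"
            )
    if protrusion_at is not None and (
        not (1 <= protrusion_at <= m) or protrusion_at in (10, 11)
    ):
        raise ValueError("protrusion position must be non-central")

    bulge = random_dna(rng, bulge_len)
    site = list(revcomp_dna(mir[10:]) + bulge + revcomp_dna(mir[:10]))

    def site_index(p: int) -> int:
        # site index of the base pairing miRNA position p
        return m - p if p >= 11 else (m - 10) + bulge_len + (10 - p)

    for p in sorted(mismatches):
        choices = _NON_PAIRING[mir[p - 1]]
        site[site_index(p)] = choices[rng.integers(0, len(choices))]
    if protrusion_at is not None:
        site.insert(
            site_index(protrusion_at) + 1,
            "ACGT"[rng.integers(0, 4)],
        )

    site_str = "".join(site)
    end = position + len(site_str)
    if position < 0 or end > len(lncrna_seq):
        raise ValueError(
            f"site [{position}, {end}) does not fit in a "
            f"{len(lncrna_seq)}-nt sequence"
        )
    for o_start, o_end in occupied:
        if position < o_end and o_start < end:
            raise ValueError(
                f"site [{position}, {end}) overlaps previously planted "
                f"site [{o_start}, {o_end})"
            )

    out = lncrna_seq[:position] + site_str + lncrna_seq[end:]
    record = PlantedEtm(
        lncrna="",
        mirna="",
        start=position,
        end=end,
        bulge_len=bulge_len,
        mismatch_positions=tuple(sorted(mismatches)),
        rule_compliant=(
            3 <= bulge_len <= 5
            and len(mismatches) <= 4
            and _no_three_consecutive(mismatches)
            and protrusion_at is None
        ),
        violation=None,
    )
    return out, record


def _spliced_positions(t: TranscriptModel) -> List[int]:
    return [p for ex in t.exons for p in range(ex.start, ex.end)]


def _read_spliced(genome: Dict[str, List[str]], t: TranscriptModel) -> str:
    s = "".join(genome[t.chrom][p] for p in _spliced_positions(t))
    return revcomp_dna(s) if t.strand == "-" else s


class _Builder:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.truth = TruthSet()

    # -- layout -----------------------------------------------------------
    def _chrom_layout(self) -> None:
        cfg = self.cfg
        n_cand = 5 * cfg.n_candidates_per_class + cfg.n_decoys
        self.n_lnc_total = cfg.n_lnc + (
            len(VIOLATION_CLASSES) if cfg.include_violations else 0
        )
        slots_per_chrom = math.ceil(cfg.n_ref_mrna / cfg.n_chromosomes)
        lncs_per_chrom = math.ceil(
            max(self.n_lnc_total, 1) / cfg.n_chromosomes
        )
        self.ref_region_end = 500 + slots_per_chrom * _SLOT
        chrom_len = self.ref_region_end + 500 + lncs_per_chrom * _LNC_SLOT + 500
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        self.genome: Dict[str, List[str]] = {
            c: list(random_dna(self.rng, chrom_len)) for c in self.chroms
        }

    def _ref_anchor(self, k: int) -> Tuple[str, int]:
        chrom = self.chroms[k % len(self.chroms)]
        return chrom, 500 + (k // len(self.chroms)) * _SLOT

    def _lnc_anchor(self, i: int) -> Tuple[str, int]:
        chrom = self.chroms[i % len(self.chroms)]
        start = self.ref_region_end + 500 + (i // len(self.chroms)) * _LNC_SLOT
        return chrom, start

    # -- reference and candidates ----------------------------------------
    def _build_reference(self) -> None:
        self.reference = []
        for k in range(self.cfg.n_ref_mrna):
            chrom, a = self._ref_anchor(k)
            exons = (
                GenomicInterval(chrom, a, a + 300, "+"),
                GenomicInterval(chrom, a + 500, a + 900, "+"),
                GenomicInterval(chrom, a + 1200, a + 1500, "+"),
            )
            self.reference.append(
                TranscriptModel(id=f"mrna_{k + 1}", exons=exons)
            )

    def _candidate_exons(
        self, code: str, chrom: str, a: int
    ) -> Tuple[GenomicInterval, ...]:
        if code == "i":
            return (GenomicInterval(chrom, a + 950, a + 1150, "+"),)
        if code == "j":
            return (
                GenomicInterval(chrom, a + 100, a + 300, "+"),
                GenomicInterval(chrom, a + 500, a + 700, "+"),
            )
        if code == "o":
            return (GenomicInterval(chrom, a + 150, a + 400, "+"),)
        if code == "u":
            return (GenomicInterval(chrom, a + 2000, a + 2300, "+"),)
        if code == "x":
            return (GenomicInterval(chrom, a + 1250, a + 1460, "-"),)
        raise AssertionError(code)

    def _build_candidates(self) -> None:
        cfg = self.cfg
        self.candidates = []
        ref_idx = 0
        for code in "ijoux":
            for k in range(cfg.n_candidates_per_class):
                ref = self.reference[ref_idx]
                chrom, a = self._ref_anchor(ref_idx)
                ref_idx += 1
                tid = f"cand_{code}_{k + 1}"
                self.candidates.append(
                    TranscriptModel(
                        id=tid,
                        exons=self._candidate_exons(code, chrom, a),
                        read_support=cfg.candidate_read_support,
                    )
                )
                self.truth.class_code_truth[tid] = code
        for k in range(cfg.n_decoys):
            ref = self.reference[ref_idx]
            ref_idx += 1
            tid = f"decoy_{k + 1}"
            self.candidates.append(
                TranscriptModel(
                    id=tid,
                    exons=ref.exons,
                    read_support=cfg.candidate_read_support,
                )
            )
            self.truth.class_code_truth[tid] = "="

    # -- planted cleavage sites ------------------------------------------
    def _plant_cleavage(self) -> None:
        cfg = self.cfg
        m = cfg.mirna_length
        for i, mid in enumerate(sorted(self.mirnas)):
            ref = self.reference[i % cfg.n_ref_mrna]
            mir = self.mirnas[mid]
            site = list(revcomp_dna(mir))
            penalty = 0.0
            if i % 2 == 1:  # one mismatch at position 5, inside the core
                p = 5
                choices = _NON_PAIRING[mir[p - 1]]
                site[m - p] = choices[self.rng.integers(0, len(choices))]
                penalty = 2.0  # weight 1.0 x core multiplier 2.0
            self._write_spliced(ref, 720, "".join(site))
            self.truth.planted_cleavage_sites.append(
                PlantedCleavage(ref.id, mid, 720, penalty, True)
            )
        # one deliberately failing site: five core mismatches, penalty 10
        if cfg.n_ref_mrna > cfg.n_mirna:
            ref = self.reference[cfg.n_mirna]
            mid = sorted(self.mirnas)[0]
            mir = self.mirnas[mid]
            site = list(revcomp_dna(mir))
            for p in (3, 5, 7, 9, 12):
                choices = _NON_PAIRING[mir[p - 1]]
                site[m - p] = choices[self.rng.integers(0, len(choices))]
            self._write_spliced(ref, 720, "".join(site))
            self.truth.planted_cleavage_sites.append(
                PlantedCleavage(ref.id, mid, 720, 10.0, False)
            )

    def _write_spliced(
        self, t: TranscriptModel, spliced_pos: int, sub: str
    ) -> None:
        positions = _spliced_positions(t)  # all references are '+'
        for i, base in enumerate(sub):
            self.genome[t.chrom][positions[spliced_pos + i]] = base

    # -- non-coding enforcement ------------------------------------------
    def _force_noncoding(self, t: TranscriptModel) -> None:
        positions = _spliced_positions(t)
        for _ in range(200):
            seq = _read_spliced(self.genome, t)
            if not coding_potential_score(seq).is_coding:
                return
            fresh = random_dna(self.rng, len(positions))
            for p, base in zip(positions, fresh):
                self.genome[t.chrom][p] = base
        raise RuntimeError(
            f"could not draw a non-coding sequence for {t.id}"
        )

    # -- lncRNAs with planted mimic sites --------------------------------
    def _compliant_plan(self, i: int) -> Tuple[int, Tuple[int, ...]]:
        cfg = self.cfg
        lo, hi = cfg.bulge_length_range
        bulge = lo + (i % (hi - lo + 1))
        k = cfg.planted_mismatch_counts[i % len(cfg.planted_mismatch_counts)]
        pool = (3, 7, 13, 5)  # non-central, never three consecutive
        return bulge, pool[:k]

    def _violation_plan(self, cls: str):
        # (bulge_len, mismatches, protrusion_at)
        m = self.cfg.mirna_length
        if cls == "bulge_short":
            return 2, (), None
        if cls == "bulge_long":
            return 6, (), None
        if cls == "mismatch_budget":
            return 4, (2, 5, 8, 13, min(15, m)), None
        if cls == "consecutive_mismatches":
            return 4, (3, 4, 5), None
        if cls == "protrusion":
            return 4, (), min(15, m)
        raise AssertionError(cls)

    def _build_lncrnas(self) -> None:
        cfg = self.cfg
        mids = sorted(self.mirnas)
        plans = []  # (tid, [(mirna, pos, bulge, mism, protrusion, violation)])
        for i in range(cfg.n_lnc):
            bulge, mism = self._compliant_plan(i)
            sites = [(mids[i % len(mids)], 100, bulge, mism, None, None)]
            if i == 0 and len(mids) > 1:
                sites.append((mids[1], 300, 3, (), None, None))
            plans.append((f"lnc_{i + 1}", sites))
        if cfg.include_violations:
            for j, cls in enumerate(VIOLATION_CLASSES):
                bulge, mism, prot = self._violation_plan(cls)
                plans.append(
                    (
                        f"lncviol_{cls}",
                        [(mids[j % len(mids)], 100, bulge, mism, prot, cls)],
                    )
                )

        self.lncrnas = []
        for idx, (tid, sites) in enumerate(plans):
            chrom, start = self._lnc_anchor(idx)
            for _ in range(200):
                seq = random_dna(self.rng, _LNC_LEN)
                records = []
                occupied: List[Tuple[int, int]] = []
                for mid, pos, bulge, mism, prot, violation in sites:
                    seq, rec = plant_mimic_site(
                        seq,
                        self.mirnas[mid],
                        pos,
                        bulge,
                        mism,
                        rng=self.rng,
                        occupied=occupied,
                        protrusion_at=prot,
                    )
                    rec.lncrna = tid
                    rec.mirna = mid
                    rec.violation = violation
                    records.append(rec)
                    occupied.append((rec.start, rec.end))
                if not coding_potential_score(seq).is_coding:
                    break
            else:
                raise RuntimeError(f"could not build non-coding {tid}")
            for p, base in zip(range(start, start + len(seq)), seq):
                self.genome[chrom][p] = base
            self.lncrnas.append(
                TranscriptModel(
                    id=tid,
                    exons=(
                        GenomicInterval(chrom, start, start + len(seq), "+"),
                    ),
                    read_support=cfg.candidate_read_support,
                )
            )
            self.truth.planted_etm_sites.extend(records)

    # -- planted differential expression ---------------------------------
    def _plant_de(self) -> None:
        cfg = self.cfg
        lfc = cfg.planted_log2fc
        for i, t in enumerate(self.lncrnas[: cfg.n_lnc]):
            self.truth.planted_de[t.id] = {
                "tolerant": lfc,
                "sensitive": -lfc if i % 2 == 0 else 0.0,
            }
        targeted = {pc.mrna for pc in self.truth.planted_cleavage_sites}
        for i, ref in enumerate(self.reference):
            if ref.id in targeted:
                sign = 1.0 if i % 2 == 0 else -1.0
                self.truth.planted_de[ref.id] = {
                    "tolerant": sign * lfc,
                    "sensitive": sign * lfc,
                }

    # -- orchestration ----------------------------------------------------
    def build(self) -> SyntheticDataset:
        cfg = self.cfg
        self._chrom_layout()
        self.mirnas = {
            f"mir_{i + 1}": random_dna(self.rng, cfg.mirna_length)
            for i in range(cfg.n_mirna)
        }
        self._build_reference()
        self._build_candidates()
        self._plant_cleavage()
        for c in self.candidates:
            if self.truth.class_code_truth[c.id] != "=":
                self._force_noncoding(c)
        self._build_lncrnas()
        self._plant_de()

        def attach(t: TranscriptModel) -> TranscriptModel:
            t.sequence = _read_spliced(self.genome, t)
            return t

        reference = [attach(t) for t in self.reference]
        candidates = [attach(t) for t in self.candidates]
        lncrnas = [attach(t) for t in self.lncrnas]

        lengths = {
            t.id: t.length for t in [*reference, *candidates, *lncrnas]
        }
        expression = simulate_counts(cfg, self.truth, lengths, rng=self.rng)
        return SyntheticDataset(
            config=cfg,
            reference=reference,
            candidates=candidates,
            lncrnas=lncrnas,
            mirnas=self.mirnas,
            truth=self.truth,
            expression=expression,
        )


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset for ``config``."""
    return _Builder(config or SimulationConfig()).build()


def generate_reference(
    config: SimulationConfig | None = None,
) -> Tuple[List[TranscriptModel], List[TranscriptModel], TruthSet]:
    """Reference annotation + engineered candidates + ground truth.

    A convenience projection of :func:`simulate` for callers that only need
    the identification-stage inputs.
    """
    ds = simulate(config)
    return ds.reference, ds.candidates, ds.truth


def build_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for g in GENOTYPES:
        for c in CONDITIONS:
            for r in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample": f"{g}-{c}-{r}",
                        "genotype": g,
                        "condition": c,
                        "replicate": r,
                    }
                )
    frame = pd.DataFrame(rows).set_index("sample")
    return SampleDesign(frame)


def simulate_counts(
    config: SimulationConfig,
    truth: TruthSet,
    lengths: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
) -> ExpressionTable:
    """Negative-binomial counts for every transcript in ``lengths``.

    Transcripts absent from ``truth.planted_de`` default to log2fc = 0 in
    every contrast. Sample columns follow the genotype x condition x
    replicate design of ``config``.
    """
    if not lengths:
        raise ValueError("no transcripts to simulate")
    rng = rng or np.random.default_rng(config.seed + 1)
    design = build_design(config)
    tids = list(lengths)
    n_t = len(tids)

    baseline = config.mean_expression * np.exp2(
        rng.normal(0.0, config.expression_log2_sd, size=n_t)
    )
    depth = config.library_size * np.exp2(
        rng.normal(0.0, 0.05, size=len(design.samples))
    )

    lfc = np.zeros((n_t, len(design.samples)))
    for j, sid in enumerate(design.samples):
        g = design.frame.loc[sid, "genotype"]
        if design.frame.loc[sid, "condition"] == "salt":
            for i, tid in enumerate(tids):
                lfc[i, j] = truth.planted_de.get(tid, {}).get(g, 0.0)

    len_kb = np.array([lengths[t] for t in tids]) / 1e3
    mu = (
        baseline[:, None]
        * np.exp2(lfc)
        * len_kb[:, None]
        * (depth[None, :] / 1e6)
    )
    n_param = 1.0 / config.dispersion
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=tids, columns=design.samples)
    return ExpressionTable(
        counts=counts_df,
        lengths=pd.Series({t: int(lengths[t]) for t in tids}),
        design=design,
        baseline_fpkm=pd.Series(baseline, index=tids),
    )
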