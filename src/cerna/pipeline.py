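"""Stage orchestration: simulate -> identify -> DE -> sites -> network.

Each stage is a pure function of its declared input files and the pipeline
configuration; the run manifest records a SHA-256 checksum and row count
per output so that re-running with an identical configuration and seed can
be verified byte-for-byte. A failing stage moves its partial outputs into a
``quarantine/`` directory so they are never silently reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .diffexpr import call_differential, ExpressionTable
from .identify import identify_lncrnas
from .io import (
    attach_sequences,
    read_counts_tsv,
    read_design_tsv,
    read_fasta,
    read_gtf,
    write_counts_tsv,
    write_design_tsv,
    write_fasta,
    write_gtf,
)
from .mimic import predict_cleavage_sites, predict_etm_sites
from .network import build_network, network_stats, write_graphml, write_triples_tsv
from .synthetic import simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "identify", "de", "targets", "mimics", "network")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: Dict[str, Dict] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @property
    def checksums(self) -> Dict[str, str]:
        """Flat path -> sha256 map across all stages."""
        out = {}
        for stage in sorted(self.stages):
            out.update(self.stages[stage].get("outputs", {}))
        return out

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()


def _count_rows(path: Path) -> int:
    if path.suffix in {".tsv", ".gtf"}:
        with open(path) as fh:
            return sum(1 for _ in fh)
    return 0


class PipelineRunner:
    """Executes stages in dependency order inside one output directory."""

    def __init__(self, config: PipelineConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(
            config_hash=_config_hash(config),
            version=__version__,
            seed=config.seed,
        )

    def path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> List[Path]:
        ds = simulate(self.config.simulate)
        p = self.path
        write_gtf(ds.reference, p("reference.gtf"))
        write_gtf([*ds.candidates, *ds.lncrnas], p("candidates.gtf"))
        write_fasta(ds.sequences, p("transcripts.fasta"))
        write_fasta(ds.mirnas, p("mirnas.fasta"))
        write_counts_tsv(ds.expression.counts, p("counts.tsv"))
        write_design_tsv(ds.expression.design, p("design.tsv"))
        pd.DataFrame(
            sorted(ds.truth.class_code_truth.items()),
            columns=["transcript_id", "class_code"],
        ).to_csv(p("truth_class_codes.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in ds.truth.planted_etm_sites]
        ).to_csv(p("truth_etm_sites.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in ds.truth.planted_cleavage_sites]
        ).to_csv(p("truth_cleavage_sites.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {"transcript_id": tid, "genotype": g, "log2fc": v}
                for tid, per_g in sorted(ds.truth.planted_de.items())
                for g, v in sorted(per_g.items())
            ]
        ).to_csv(p("truth_de.tsv"), sep="\t", index=False)
        return [
            p(n)
            for n in (
                "reference.gtf",
                "candidates.gtf",
                "transcripts.fasta",
                "mirnas.fasta",
                "counts.tsv",
                "design.tsv",
                "truth_class_codes.tsv",
                "truth_etm_sites.tsv",
                "truth_cleavage_sites.tsv",
                "truth_de.tsv",
            )
        ]

    def stage_identify(self) -> List[Path]:
        p = self.path
        seqs = read_fasta(p("transcripts.fasta"))
        reference = read_gtf(p("reference.gtf"))
        candidates = attach_sequences(read_gtf(p("candidates.gtf")), seqs)
        retained, reports, table = identify_lncrnas(
            candidates, reference, self.config.identify
        )
        write_fasta({t.id: t.sequence for t in retained}, p("lncrnas.fasta"))
        table.to_csv(p("class_codes.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "stage": r.stage,
                    "input": r.input_count,
                    "retained": r.retained_count,
                    "rejected": len(r.rejected),
                }
                for r in reports
            ]
        ).to_csv(p("filter_report.tsv"), sep="\t", index=False)
        return [p("lncrnas.fasta"), p("class_codes.tsv"), p("filter_report.tsv")]

    def _expression(self) -> ExpressionTable:
        counts = read_counts_tsv(self.path("counts.tsv"))
        design = read_design_tsv(self.path("design.tsv"))
        seqs = read_fasta(self.path("transcripts.fasta"))
        lengths = pd.Series({tid: len(s) for tid, s in seqs.items()})
        return ExpressionTable(counts=counts, lengths=lengths, design=design)

    def stage_de(self) -> List[Path]:
        table = self._expression()
        outputs = []
        for contrast in self.config.contrasts:
            res = call_differential(
                table,
                table.design.group(contrast.genotype, contrast.condition_a),
                table.design.group(contrast.genotype, contrast.condition_b),
                self.config.de,
            )
            out = self.path(f"de_{contrast.name}.tsv")
            res.to_csv(out, sep="\t", index_label="transcript_id")
            outputs.append(out)
        return outputs

    def stage_targets(self) -> List[Path]:
        mirnas = read_fasta(self.path("mirnas.fasta"))
        seqs = read_fasta(self.path("transcripts.fasta"))
        ref_ids = [t.id for t in read_gtf(self.path("reference.gtf"))]
        mrnas = {tid: seqs[tid] for tid in ref_ids}
        sites = predict_cleavage_sites(mirnas, mrnas, self.config.cleavage)
        out = self.path("cleavage_sites.tsv")
        sites.to_csv(out, sep="\t", index=False)
        return [out]

    def stage_mimics(self) -> List[Path]:
        mirnas = read_fasta(self.path("mirnas.fasta"))
        lncrnas = read_fasta(self.path("lncrnas.fasta"))
        sites = predict_etm_sites(mirnas, lncrnas, self.config.mimic)
        out = self.path("etm_sites.tsv")
        sites.to_csv(out, sep="\t", index=False)
        return [out]

    def stage_network(self) -> List[Path]:
        p = self.path
        etm = pd.read_csv(p("etm_sites.tsv"), sep="\t")
        cleav = pd.read_csv(p("cleavage_sites.tsv"), sep="\t")
        de_frames = {
            c.genotype: pd.read_csv(
                p(f"de_{c.name}.tsv"), sep="\t", index_col="transcript_id"
            )
            for c in self.config.contrasts
        }

        def merged_call(tid: str) -> str:
            for g in sorted(de_frames):
                if tid in de_frames[g].index:
                    call = str(de_frames[g].loc[tid, "call"])
                    if call != "ns":
                        return call
            return "ns"

        merged = pd.DataFrame(
            {
                "call": {
                    tid: merged_call(tid)
                    for g in de_frames
                    for tid in de_frames[g].index
                }
            }
        )
        net = build_network(
            etm, cleav, merged, merged, self.config.network
        )
        write_triples_tsv(net, p("triples.tsv"))
        write_graphml(net, p("network.graphml"))
        stats = network_stats(net)
        with open(p("network_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
        return [p("triples.tsv"), p("network.graphml"), p("network_stats.json")]

    # -- orchestration ----------------------------------------------------

    def run_stage(self, name: str) -> None:
        fn: Callable[[], List[Path]] = getattr(self, f"stage_{name}")
        logger.info("stage %s: starting", name)
        t0 = time.monotonic()
        try:
            outputs = fn()
        except Exception as exc:
            self._quarantine(name)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        self.manifest.stages[name] = {
            "outputs": {o.name: _sha256(o) for o in outputs},
            "row_counts": {o.name: _count_rows(o) for o in outputs},
            "seconds": round(time.monotonic() - t0, 3),
        }
        logger.info("stage %s: wrote %d file(s)", name, len(outputs))

    def _quarantine(self, stage: str) -> None:
        qdir = self.outdir / "quarantine" / stage
        known = {
            "simulate": [
                "reference.gtf",
                "candidates.gtf",
                "transcripts.fasta",
                "mirnas.fasta",
                "counts.tsv",
                "design.tsv",
            ],
            "identify": ["lncrnas.fasta", "class_codes.tsv", "filter_report.tsv"],
            "targets": ["cleavage_sites.tsv"],
            "mimics": ["etm_sites.tsv"],
            "network": ["triples.tsv", "network.graphml", "network_stats.json"],
        }.get(stage, [])
        moved = False
        for name in known:
            src = self.outdir / name
            if src.exists():
                qdir.mkdir(parents=True, exist_ok=True)
                shutil.move(str(src), str(qdir / name))
                moved = True
        if moved:
            logger.warning(
                "stage %s failed; partial outputs moved to %s", stage, qdir
            )

    def run(self, stages=STAGES) -> RunManifest:
        self.manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        for name in stages:
            self.run_stage(name)
        self.manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.path("manifest.json"), "w") as fh:
            fh.write(self.manifest.to_json())
        return self.manifest


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path = "cerna_out",
    stages=STAGES,
) -> RunManifest:
    """Run the configured stages and return the manifest."""
    return PipelineRunner(config or PipelineConfig(), outdir).run(stages)
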