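"""FPKM computation and per-contrast differential-expression calls.

Expression is summarised as FPKM (fragments per kilobase of exon model per
million mapped fragments), computed from raw counts as

    fpkm[t, s] = counts[t, s] * 1e9 / (total_counts[s] * length[t])

with the per-sample total counted fragments as library size. A transcript
is called differentially expressed between two sample groups when
|log2 fold-change| > 1 (strict) and p < 0.05 (strict), where the fold
change is computed on group-mean FPKM with a pseudocount of 1 and the
p-value comes from a two-sided Welch t-test on log2(FPKM + 1) across
replicates. Raw p-values drive the calls; a Benjamini-Hochberg FDR column
is reported for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("tolerant", "sensitive")
CONDITIONS = ("control", "salt")


@dataclass
class SampleDesign:
    """Sample metadata: genotype x condition x replicate per sample id."""

    frame: pd.DataFrame  # index: sample id; columns: genotype, condition, replicate

    def __post_init__(self) -> None:
        required = {"genotype", "condition", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design is missing columns {sorted(missing)}")
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids {dups}")
        sizes = self.frame.groupby(["genotype", "condition"]).size()
        too_small = sizes[sizes < 2]
        if len(too_small):
            raise ValueError(
                "every (genotype, condition) group needs >= 2 replicates; "
                f"offending groups: {too_small.to_dict()}"
            )

    @property
    def samples(self) -> List[str]:
        return list(self.frame.index)

    def group(self, genotype: str, condition: str) -> List[str]:
        sel = (self.frame["genotype"] == genotype) & (
            self.frame["condition"] == condition
        )
        return list(self.frame.index[sel])


@dataclass
class ExpressionTable:
    """Counts, lengths and design for one experiment; FPKM derived on access."""

    counts: pd.DataFrame  # transcripts x samples, non-negative integers
    lengths: pd.Series  # nt per transcript
    design: SampleDesign
    baseline_fpkm: Optional[pd.Series] = None  # simulation ground truth

    def __post_init__(self) -> None:
        if list(self.counts.columns) != self.design.samples:
            raise ValueError("count columns do not match the design samples")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise ValueError(
                f"lengths missing for transcripts {sorted(missing)[:5]} ..."
            )
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self._fpkm: Optional[pd.DataFrame] = None

    @property
    def fpkm(self) -> pd.DataFrame:
        if self._fpkm is None:
            self._fpkm = compute_fpkm(
                self.counts, self.lengths.loc[self.counts.index]
            )
        return self._fpkm


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM layer from raw counts; errors name any zero-size library."""
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive transcript lengths: {bad[:5]}")
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero library size in sample(s) {zero}")
    denom = totals.values[None, :] * lengths.values[:, None]
    return counts * 1e9 / denom


@dataclass
class DEParams:
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    pseudocount: float = 1.0


def call_differential(
    table: ExpressionTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Per-transcript DE results for the contrast B vs A.

    Returns a frame indexed by transcript with columns ``mean_a``,
    ``mean_b``, ``log2fc``, ``p``, ``fdr`` and ``call`` (up/down/ns).
    Groups with zero variance on the log scale are handled explicitly:
    equal means give p = 1, unequal means with no within-group noise give
    p = 0.
    """
    params = params or DEParams()
    for g, name in ((group_a, "A"), (group_b, "B")):
        if len(g) < 2:
            raise ValueError(f"group {name} needs >= 2 replicates")
        unknown = set(g) - set(table.counts.columns)
        if unknown:
            raise ValueError(f"group {name}: unknown samples {sorted(unknown)}")

    fpkm = table.fpkm
    fa = fpkm[list(group_a)].values
    fb = fpkm[list(group_b)].values
    mean_a = fa.mean(axis=1)
    mean_b = fb.mean(axis=1)
    eps = params.pseudocount
    log2fc = np.log2((mean_b + eps) / (mean_a + eps))

    la = np.log2(fa + 1.0)
    lb = np.log2(fb + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows are resolved explicitly below; silence scipy's
        # catastrophic-cancellation warning for them
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    var_a = la.var(axis=1, ddof=1)
    var_b = lb.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p = np.where(
        degenerate,
        np.where(la.mean(axis=1) == lb.mean(axis=1), 1.0, 0.0),
        p,
    )
    p = np.nan_to_num(p, nan=1.0)

    fdr = stats.false_discovery_control(p, method="bh")
    call = np.where(
        (log2fc > params.lfc_threshold) & (p < params.alpha),
        "up",
        np.where(
            (log2fc < -params.lfc_threshold) & (p < params.alpha),
            "down",
            "ns",
        ),
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "call": call,
        },
        index=fpkm.index,
    )


def contrast_salt_vs_control(
    table: ExpressionTable, genotype: str, params: DEParams | None = None
) -> pd.DataFrame:
    """Convenience wrapper: salt vs control within one genotype."""
    return call_differential(
        table,
        table.design.group(genotype, "control"),
        table.design.group(genotype, "salt"),
        params,
    )
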