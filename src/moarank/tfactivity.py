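"""Fold-change computation and activated-transcription-factor inference.

A transcription factor is called *activated* when the mean differential
expression of its most responsive target genes meets a threshold: for TFs with
three or more target genes present in the profile, the mean of the three
largest values; for TFs with one or two, the mean of all of them. The same
rule runs in two modes — ``ratio`` (case-mean / control-mean fold changes for
a patient sample) and ``zscore`` (drug-instance differential-expression
z-scores standing in for fold changes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .io import ExpressionMatrix, TFTargetMap

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeProfile",
    "TFActivation",
    "compute_fold_change",
    "activation_score",
    "identify_activated_tfs",
    "upregulated_targets",
]

#: number of top-responding targets averaged for TFs with enough targets
TOP_K_TARGETS = 3

#: default activation-score threshold T and up-regulation fold-change cutoff
DEFAULT_THRESHOLD = 2.0


@dataclass
class FoldChangeProfile:
    """Per-gene differential expression: fold-change ratios or z-scores."""

    values: pd.Series  # index: gene symbol
    mode: Literal["ratio", "zscore"] = "ratio"

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    def __getitem__(self, gene: str) -> float:
        return float(self.values[gene])

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)


@dataclass
class TFActivation:
    """Activation call for one transcription factor."""

    tf: str
    score: float
    activated: bool
    contributing_targets: tuple[str, ...]


def compute_fold_change(expr: ExpressionMatrix) -> FoldChangeProfile:
    """Per-gene (case mean) / (control mean) fold change.

    Genes whose control mean is zero have no defined ratio; they are dropped
    from the profile and counted in the log.
    """
    case = expr.values[expr.case_ids].mean(axis=1)
    control = expr.values[expr.control_ids].mean(axis=1)
    zero = control == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.info("dropped %d genes with zero control mean", n_zero)
    fc = case[~zero] / control[~zero]
    if fc.empty:
        raise ValueError("no genes with non-zero control mean; cannot form fold changes")
    return FoldChangeProfile(values=fc, mode="ratio")


def _available_targets(tf: str, profile: FoldChangeProfile, tfmap: TFTargetMap) -> list[str]:
    if tf not in tfmap:
        raise KeyError(f"transcription factor {tf!r} not in TF-target map")
    return [g for g in tfmap[tf] if g in profile]


def activation_score(
    tf: str, profile: FoldChangeProfile, tfmap: TFTargetMap
) -> tuple[float, tuple[str, ...]]:
    """Activation score of ``tf`` and the target genes that contributed.

    Mean of the 3 largest target values when the TF has >= 3 targets present
    in the profile, otherwise the mean of all present targets. Returns
    ``(nan, ())`` when no target of the TF appears in the profile (the TF is
    skipped by :func:`identify_activated_tfs`). Ties at the 3rd-largest value
    are broken by lexicographic gene symbol; the score itself is unaffected.
    """
    avail = _available_targets(tf, profile, tfmap)
    if not avail:
        return math.nan, ()
    ranked = sorted(avail, key=lambda g: (-profile[g], g))
    chosen = tuple(ranked[:TOP_K_TARGETS]) if len(ranked) >= TOP_K_TARGETS else tuple(ranked)
    score = sum(profile[g] for g in chosen) / len(chosen)
    return float(score), chosen


def identify_activated_tfs(
    profile: FoldChangeProfile,
    tfmap: TFTargetMap,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[TFActivation]:
    """Score every TF with at least one profiled target; call those with
    score >= ``threshold`` activated (the cutoff is inclusive)."""
    if threshold <= 0:
        raise ValueError("activation threshold must be positive")
    if not tfmap.targets:
        raise ValueError("empty TF-target map")
    out: list[TFActivation] = []
    n_skipped = 0
    for tf in tfmap.tfs:
        score, chosen = activation_score(tf, profile, tfmap)
        if math.isnan(score):
            n_skipped += 1
            continue
        out.append(
            TFActivation(
                tf=tf,
                score=score,
                activated=score >= threshold,
                contributing_targets=chosen,
            )
        )
    if n_skipped:
        logger.info("skipped %d TFs with no target present in the profile", n_skipped)
    return out


def upregulated_targets(
    activated: Iterable[TFActivation],
    profile: FoldChangeProfile,
    tfmap: TFTargetMap,
    fc_threshold: float = DEFAULT_THRESHOLD,
) -> set[str]:
    """Union, over activated TFs, of their targets whose profile value meets
    ``fc_threshold`` (inclusive)."""
    if fc_threshold <= 0:
        raise ValueError("up-regulation threshold must be positive")
    out: set[str] = set()
    for act in activated:
        if not act.activated:
            continue
        for g in tfmap[act.tf]:
            if g in profile and profile[g] >= fc_threshold:
                out.add(g)
    return out


def regulators_of(
    targets: set[str], activated: Iterable[TFActivation], tfmap: TFTargetMap
) -> dict[str, set[str]]:
    """Map each activated TF to the subset of ``targets`` it regulates."""
    out: dict[str, set[str]] = {}
    for act in activated:
        if not act.activated:
            continue
        regulated = set(tfmap[act.tf]) & targets
        if regulated:
            out[act.tf] = regulated
    return out


def write_activation_report(activations: Iterable[TFActivation], path) -> None:
    """TSV report: tf, score, activated, contributing_targets (comma-joined)."""
    rows = [
        {
            "tf": a.tf,
            "score": a.score,
            "activated": a.activated,
            "contributing_targets": ",".join(a.contributing_targets),
        }
        for a in activations
    ]
    pd.DataFrame(rows, columns=["tf", "score", "activated", "contributing_targets"]).to_csv(
        path, sep="\t", index=False
    )
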