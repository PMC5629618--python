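"""Screening-based evaluation: active-drug labelling and top-k enrichment.

A screened drug is *active* when its mean growth rate lies at or below
``mean - k_sd * sd`` of all screened growth rates (lower growth = stronger
suppression). Enrichment compares the number and fraction of actives among
the top-k ranked drugs with the expectation under uniform random selection
(the hypergeometric mean ``k * n_active / n_total``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ScreeningTable
from .scoring import RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "ActiveLabelSet",
    "EnrichmentCurve",
    "active_threshold",
    "classify_actives",
    "topk_metrics",
    "random_expectation",
]


@dataclass
class ActiveLabelSet:
    threshold: float
    actives: set[str]
    n_total: int  # number of screened drugs evaluated


@dataclass
class EnrichmentCurve:
    """Actives among the top-k for each k, with the random-selection baseline.

    ``n_active`` counts the labelled actives present in the ranking; the
    baseline expected count at k is ``k * n_active / n_ranked``.
    """

    ks: list[int]
    counts: list[int]
    fractions: list[float]
    expected_counts: list[float]
    expected_fractions: list[float]
    n_active: int
    n_ranked: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "n_active_topk": self.counts,
                "fraction": self.fractions,
                "expected_count": self.expected_counts,
                "expected_fraction": self.expected_fractions,
            }
        )

    def plot(self, path) -> None:
        """Two-panel bar chart: fraction and count of actives in the top-k,
        method vs random baseline."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        x = np.arange(len(self.ks))
        fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(9, 3.5))
        w = 0.38
        ax_a.bar(x - w / 2, self.fractions, w, label="predicted")
        ax_a.bar(x + w / 2, self.expected_fractions, w, label="random")
        ax_a.set_ylabel("fraction of active drugs")
        ax_b.bar(x - w / 2, self.counts, w, label="predicted")
        ax_b.bar(x + w / 2, self.expected_counts, w, label="random")
        ax_b.set_ylabel("number of active drugs")
        for ax in (ax_a, ax_b):
            ax.set_xticks(x, [f"top-{k}" for k in self.ks])
            ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def active_threshold(growth_rates: Sequence[float], k_sd: float = 1.5, ddof: int = 1) -> float:
    """Growth-rate cutoff ``mean - k_sd * sd`` (sample sd by default;
    ``ddof=0`` gives the population sd)."""
    rates = np.asarray(growth_rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 growth rates to set an active threshold")
    return float(rates.mean() - k_sd * rates.std(ddof=ddof))


def classify_actives(screen: ScreeningTable, cutoff: float) -> ActiveLabelSet:
    """Drugs whose growth rate is at or below the cutoff (inclusive)."""
    if not np.isfinite(cutoff):
        raise ValueError("active cutoff must be finite")
    actives = {name for name, rate in screen.rates.items() if rate <= cutoff}
    return ActiveLabelSet(threshold=cutoff, actives=actives, n_total=len(screen))


def topk_metrics(
    ranked: RankedList,
    labels: ActiveLabelSet,
    ks: Sequence[int] = (30, 50, 70, 100),
    names: Mapping[str, str] | None = None,
) -> EnrichmentCurve:
    """Count labelled actives among the top-k ranks for each k.

    ``names`` maps ranking drug ids to screening drug names when the two
    vocabularies differ (matching is exact-string after trimming). Drugs in
    the ranking without a screening label simply count as inactive; unmatched
    names are logged, not guessed.
    """
    ks = list(ks)
    if sorted(ks) != ks:
        raise ValueError("ks must be sorted ascending")
    n = len(ranked)
    for k in ks:
        if k > n:
            raise ValueError(f"k={k} exceeds ranking length {n}")

    def label_name(drug_id: str) -> str:
        return (names.get(drug_id, drug_id) if names else drug_id).strip()

    active_flags = [label_name(d) in labels.actives for d in ranked.drug_ids]
    n_active = sum(active_flags)
    if n_active == 0:
        logger.warning("no labelled active drug appears in the ranking")
    counts = [sum(active_flags[:k]) for k in ks]
    expected = [random_expectation(n, n_active, k) for k in ks]
    return EnrichmentCurve(
        ks=ks,
        counts=counts,
        fractions=[c / k for c, k in zip(counts, ks)],
        expected_counts=[e[0] for e in expected],
        expected_fractions=[e[1] for e in expected],
        n_active=n_active,
        n_ranked=n,
    )


def random_expectation(n_total: int, n_active: int, k: int) -> tuple[float, float]:
    """Expected (count, fraction) of actives in a uniform random top-k: the
    hypergeometric mean ``k * n_active / n_total`` and constant fraction
    ``n_active / n_total``."""
    if not (0 <= n_active <= n_total):
        raise ValueError("need 0 <= n_active <= n_total")
    if not (0 < k <= n_total):
        raise ValueError("need 0 < k <= n_total")
    frac = n_active / n_total
    return k * frac, frac
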