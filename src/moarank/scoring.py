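"""Drug sensitivity scoring by MoAnet / Pnet node overlap.

For drug *i* with instance networks MoAnet_i^j (j = 1..N_i) and a patient
network Pnet, the sensitivity score is

    S_i = sum_j |nodes(MoAnet_i^j) ∩ nodes(Pnet)| / (|nodes(Pnet)| * N_i)

i.e. the mean fraction of the patient network recovered by the drug's
mechanism-of-action networks. S_i lies in [0, 1]; drugs are ranked by
decreasing score, ties broken by drug id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import DrugCatalog, InstanceProfileSet
from .netbuild import SignalingNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityScore",
    "RankedList",
    "filter_instances",
    "node_overlap",
    "sensitivity_score",
    "rank_drugs",
    "score_drugs",
]


@dataclass
class SensitivityScore:
    drug_id: str
    score: float
    n_instances: int
    per_instance: list[tuple[str, int]]  # (instance id, overlap node count)


@dataclass
class RankedList:
    """Drugs in decreasing score order, ranks 1..n with no gaps."""

    entries: list[tuple[int, str, float]]  # (rank, drug_id, score)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def drug_ids(self) -> list[str]:
        return [d for _, d, _ in self.entries]

    def rank_of(self, drug_id: str) -> int:
        for r, d, _ in self.entries:
            if d == drug_id:
                return r
        raise KeyError(drug_id)

    def top(self, k: int) -> list[str]:
        return [d for r, d, _ in self.entries if r <= k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rank", "drug_id", "score"])


def filter_instances(
    instances: InstanceProfileSet,
    time_h: float | None = 24,
    dose_label: str | None = "10 uM",
    exclude_cell_line: str | None = None,
) -> InstanceProfileSet:
    """Keep instances at the given treatment time and dose label, excluding
    the patient's own cell line (to avoid scoring a drug by its profile on
    the very line being predicted for). Dose labels are compared verbatim.
    Passing ``None`` for a field disables that filter."""
    meta = instances.metadata
    keep = pd.Series(True, index=meta.index)
    if time_h is not None:
        keep &= meta["time_h"] == time_h
    if dose_label is not None:
        keep &= meta["dose"].str.strip() == dose_label
    if exclude_cell_line is not None:
        keep &= meta["cell_line"].str.strip() != exclude_cell_line
    dropped_drugs = set(meta["drug_id"]) - set(meta.loc[keep, "drug_id"])
    if dropped_drugs:
        logger.info(
            "instance filter removed all instances of %d drugs: %s",
            len(dropped_drugs),
            sorted(dropped_drugs),
        )
    return instances.subset(meta.index[keep])


def node_overlap(moanet: SignalingNetwork, pnet: SignalingNetwork) -> int:
    """Number of genes common to both networks (roles ignored)."""
    return len(moanet.nodes & pnet.nodes)


def sensitivity_score(
    drug_id: str,
    instance_networks: list[SignalingNetwork],
    pnet: SignalingNetwork,
) -> SensitivityScore:
    """Average Pnet-normalised node overlap across a drug's instances."""
    if not instance_networks:
        raise ValueError(f"drug {drug_id}: no instance networks to score")
    size = pnet.n_nodes
    if size == 0:
        raise ValueError("empty Pnet")
    per_instance = [
        (net.provenance.get("instance_id", str(j)), node_overlap(net, pnet))
        for j, net in enumerate(instance_networks)
    ]
    score = sum(c for _, c in per_instance) / (size * len(per_instance))
    return SensitivityScore(
        drug_id=drug_id,
        score=score,
        n_instances=len(per_instance),
        per_instance=per_instance,
    )


def rank_drugs(scores: list[SensitivityScore]) -> RankedList:
    """Sort by score descending, ties by drug id ascending; ranks 1..n."""
    if not scores:
        raise ValueError("no scores to rank")
    ids = [s.drug_id for s in scores]
    if len(set(ids)) != len(ids):
        dup = sorted({d for d in ids if ids.count(d) > 1})
        raise ValueError(f"duplicate drug ids in scores: {dup}")
    ordered = sorted(scores, key=lambda s: (-s.score, s.drug_id))
    return RankedList(entries=[(r, s.drug_id, s.score) for r, s in enumerate(ordered, 1)])


def score_drugs(
    instances: InstanceProfileSet,
    pnet: SignalingNetwork,
    catalog: DrugCatalog,
    build_instance_network,
) -> tuple[RankedList, list[SensitivityScore]]:
    """Score and rank every drug with at least one scorable instance.

    ``build_instance_network(instance_id)`` must return a
    :class:`SignalingNetwork` or ``None`` (instance skipped). Drugs whose
    instances all fail to yield a network are dropped with a log entry.
    """
    by_drug: dict[str, list[SignalingNetwork]] = {}
    for iid in instances.instance_ids:
        net = build_instance_network(iid)
        if net is None:
            continue
        by_drug.setdefault(instances.metadata.at[iid, "drug_id"], []).append(net)
    skipped = sorted(set(instances.metadata["drug_id"]) - set(by_drug))
    if skipped:
        logger.info("%d drugs yielded no instance network: %s", len(skipped), skipped)
    if not by_drug:
        raise ValueError("no drug yielded any instance network; nothing to score")
    scores = [
        sensitivity_score(drug_id, nets, pnet) for drug_id, nets in sorted(by_drug.items())
    ]
    return rank_drugs(scores), scores


def write_score_table(
    ranked: RankedList,
    scores: list[SensitivityScore],
    catalog: DrugCatalog | None,
    path,
) -> None:
    """Score table TSV: rank, drug_id, drug_name, score, n_instances."""
    by_id = {s.drug_id: s for s in scores}
    rows = []
    for rank, drug_id, score in ranked.entries:
        name = catalog[drug_id].name if catalog is not None and drug_id in catalog else drug_id
        rows.append(
            {
                "rank": rank,
                "drug_id": drug_id,
                "drug_name": name,
                "score": score,
                "n_instances": by_id[drug_id].n_instances,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_per_instance_table(scores: list[SensitivityScore], path) -> None:
    rows = [
        {"drug_id": s.drug_id, "instance_id": iid, "overlap": c}
        for s in scores
        for iid, c in s.per_instance
    ]
    pd.DataFrame(rows, columns=["drug_id", "instance_id", "overlap"]).to_csv(
        path, sep="\t", index=False
    )
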