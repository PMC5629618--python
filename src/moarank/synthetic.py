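"""Deterministic synthetic-data generator with planted ground truth.

Emits a coherent miniature universe — interactome, TF-target map, case/control
expression, drug catalog, per-instance z-score profiles and a screening table —
in exactly the file formats the readers consume, so the whole pipeline runs
and can be verified against known answers without any download.

Planted structure
-----------------
The interactome is a hub-and-spoke scaffold plus random filler: every disease
gene and every TF is adjacent to a single hub gene, each TF's target genes are
adjacent to that TF only, and filler genes attach only to the hub or to each
other. This makes each (source, TF) shortest path unique, so the patient
network's node set is known in closed form:

    Pnet nodes = disease genes ∪ {hub} ∪ activated TFs ∪ up-regulated targets.

Each drug is assigned an overlap fraction f. Its catalog targets are the first
round(f * |Pnet|) genes of a fixed ordering of Pnet nodes (hub first, then
sources, activated TFs, up-regulated targets — the order guarantees that every
gene a path recruits is itself already among the targets), and a drug-private
TF reachable through the hub is activated in the drug's instances via private
marker genes. The resulting MoAnet therefore overlaps the Pnet by exactly
round(f * |Pnet|) nodes in noise-free mode, so the pipeline's sensitivity
score for the drug equals f up to the 1/|Pnet| rounding grid.

Drugs with f = 0 instead get a private target wired directly to their private
TF, away from the hub, giving a valid MoAnet with zero overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["FixtureSpec", "GroundTruth", "generate_fixture"]

_MARKERS_PER_DRUG = 3
_CONTROL_LEVEL = 10.0
_PLANTED_FC = 4.0  # comfortably above the activation threshold of 2
_MARKER_Z = 5.0


@dataclass
class FixtureSpec:
    """Knobs of the synthetic universe. Same seed, same spec -> byte-identical
    output files."""

    seed: int = 0
    n_disease_genes: int = 10
    n_tfs: int = 20
    n_targets_per_tf: int = 4
    planted_activated_tfs: int = 5
    n_drugs: int = 10
    n_instances_per_drug: int = 2
    n_filler_genes: int = 20
    edge_density: float = 2.0  # expected extra degree of filler genes
    graph_model: Literal["pa", "er"] = "pa"
    overlap_fractions: Sequence[float] | None = None  # default: linspace(0, 0.9)
    noise_sd: float = 0.0
    active_cutoff_fraction: float = 0.5  # drugs with f >= this are "active"
    n_screen_background: int = 40  # screened-only drugs forming the inactive bulk
    cell_lines: Sequence[str] = ("A549", "MCF7", "HT29")
    time_h: float = 24
    dose: str = "10 uM"

    def validate(self) -> None:
        counts = {
            "n_disease_genes": self.n_disease_genes,
            "n_tfs": self.n_tfs,
            "n_targets_per_tf": self.n_targets_per_tf,
            "planted_activated_tfs": self.planted_activated_tfs,
            "n_drugs": self.n_drugs,
            "n_instances_per_drug": self.n_instances_per_drug,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_filler_genes < 0:
            raise ValueError("n_filler_genes must be >= 0")
        if self.planted_activated_tfs > self.n_tfs:
            raise ValueError("planted_activated_tfs cannot exceed n_tfs")
        fr = self.fractions()
        if len(fr) != self.n_drugs:
            raise ValueError(
                f"overlap_fractions has {len(fr)} entries for {self.n_drugs} drugs"
            )
        bad = [f for f in fr if not 0 <= f <= 1]
        if bad:
            raise ValueError(f"overlap fractions must lie in [0, 1], got {bad}")

    def fractions(self) -> list[float]:
        if self.overlap_fractions is not None:
            return [float(f) for f in self.overlap_fractions]
        return [round(0.9 * i / max(self.n_drugs - 1, 1), 6) for i in range(self.n_drugs)]


@dataclass
class GroundTruth:
    """What the generator planted, for verification after a pipeline run."""

    activated_tfs: frozenset[str]
    upregulated_targets: frozenset[str]
    pnet_nodes: frozenset[str]
    overlap_fraction: dict[str, float]  # drug id -> planted f
    expected_score: dict[str, float]  # drug id -> round(f*|Pnet|)/|Pnet|
    active_drugs: frozenset[str]  # drug names with f >= cutoff
    drug_names: dict[str, str]
    case_ids: list[str] = field(default_factory=lambda: ["CASE1", "CASE2"])
    control_ids: list[str] = field(default_factory=lambda: ["CTRL1", "CTRL2"])


def _filler_edges(
    spec: FixtureSpec, rng: np.random.Generator, hub: str, fillers: list[str]
) -> list[tuple[str, str]]:
    """Attach filler genes to the hub/each other only, so planted shortest
    paths stay unique."""
    edges: list[tuple[str, str]] = []
    if not fillers:
        return edges
    if spec.graph_model == "pa":
        # preferential attachment over {hub} + fillers seen so far
        m = max(1, round(spec.edge_density / 2))
        pool = [hub]
        degree = {hub: 1}
        for f in fillers:
            weights = np.array([degree[p] for p in pool], dtype=float)
            k = min(m, len(pool))
            picks = rng.choice(len(pool), size=k, replace=False, p=weights / weights.sum())
            for idx in picks:
                p = pool[int(idx)]
                edges.append((f, p))
                degree[p] = degree.get(p, 0) + 1
            degree[f] = degree.get(f, 0) + k
            pool.append(f)
    elif spec.graph_model == "er":
        p_edge = min(1.0, spec.edge_density / max(len(fillers) - 1, 1))
        for i, a in enumerate(fillers):
            edges.append((a, hub))  # keeps every filler connected
            for b in fillers[i + 1 :]:
                if rng.random() < p_edge:
                    edges.append((a, b))
    else:
        raise ValueError(f"unknown graph model {spec.graph_model!r}")
    return edges


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> GroundTruth:
    """Write the full fixture file set to ``out_dir`` and return the planted
    truth. All randomness flows from ``spec.seed`` through one generator."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hub = "HUB"
    sources = [f"DIS{i:02d}" for i in range(spec.n_disease_genes)]
    tfs = [f"TF{i:02d}" for i in range(spec.n_tfs)]
    planted = sorted(rng.permutation(tfs)[: spec.planted_activated_tfs].tolist())
    tf_targets = {tf: [f"TG{i:02d}_{j}" for j in range(spec.n_targets_per_tf)] for i, tf in enumerate(tfs)}
    fillers = [f"FIL{i:03d}" for i in range(spec.n_filler_genes)]
    fractions = spec.fractions()
    drug_ids = [f"D{i:02d}" for i in range(spec.n_drugs)]
    drug_names = {d: f"Drug{d[1:]}" for d in drug_ids}
    drug_tfs = {d: f"DTF{i:02d}" for i, d in enumerate(drug_ids)}
    markers = {
        d: [f"MK{i:02d}_{j}" for j in range(_MARKERS_PER_DRUG)]
        for i, d in enumerate(drug_ids)
    }
    private_target = {d: f"DT{i:02d}" for i, d in enumerate(drug_ids)}

    # planted Pnet composition
    n_boost = min(3, spec.n_targets_per_tf)
    boosted = {tf: tf_targets[tf][:n_boost] for tf in planted}
    upreg = sorted(g for tf in planted for g in boosted[tf])
    pnet_nodes = [hub] + sorted(sources) + sorted(planted) + upreg
    size = len(pnet_nodes)

    counts = {d: int(round(f * size)) for d, f in zip(drug_ids, fractions)}
    infeasible = {d: c for d, c in counts.items() if c > size}
    if infeasible:
        raise ValueError(
            f"planted overlap needs more Pnet genes than exist ({size}): {infeasible}"
        )

    # --- interactome -------------------------------------------------------
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        edges.add((min(a, b), max(a, b)))

    for s in sources:
        add(s, hub)
    for tf in tfs:
        add(tf, hub)
        for g in tf_targets[tf]:
            add(g, tf)
    for d in drug_ids:
        add(drug_tfs[d], hub)
        for m in markers[d]:
            add(m, drug_tfs[d])
        if counts[d] == 0:
            add(private_target[d], drug_tfs[d])
            add(private_target[d], hub)
    for a, b in _filler_edges(spec, rng, hub, fillers):
        add(a, b)

    with open(out / "interactome.tsv", "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")

    # --- TF-target map -----------------------------------------------------
    tf_rows = [(tf, g) for tf in tfs for g in tf_targets[tf]]
    tf_rows += [(drug_tfs[d], m) for d in drug_ids for m in markers[d]]
    with open(out / "tf_targets.tsv", "w") as fh:
        for tf, g in sorted(tf_rows):
            fh.write(f"{tf}\t{g}\n")

    # --- expression --------------------------------------------------------
    all_genes = sorted(
        {hub, *sources, *tfs, *fillers}
        | {g for gs in tf_targets.values() for g in gs}
        | {drug_tfs[d] for d in drug_ids}
        | {m for ms in markers.values() for m in ms}
        | {private_target[d] for d in drug_ids if counts[d] == 0}
    )
    boosted_set = set(upreg)
    fc = pd.Series(1.0, index=all_genes)
    fc[fc.index.isin(boosted_set)] = _PLANTED_FC
    truth_case = ["CASE1", "CASE2"]
    truth_ctrl = ["CTRL1", "CTRL2"]
    expr = pd.DataFrame(index=all_genes)
    for s in truth_case:
        noise = rng.normal(0.0, spec.noise_sd, size=len(all_genes)) if spec.noise_sd else 0.0
        expr[s] = np.maximum(_CONTROL_LEVEL * (fc.to_numpy() + noise), 0.0)
    for s in truth_ctrl:
        expr[s] = _CONTROL_LEVEL
    expr.index.name = "gene"
    expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")

    with open(out / "disease_genes.txt", "w") as fh:
        for s in sorted(sources):
            fh.write(s + "\n")

    # --- drug catalog ------------------------------------------------------
    catalog_rows: list[tuple[str, str, str]] = []
    for d in drug_ids:
        c = counts[d]
        targets = pnet_nodes[:c] if c >= 1 else [private_target[d]]
        for t in targets:
            catalog_rows.append((d, drug_names[d], t))
    with open(out / "drug_catalog.tsv", "w") as fh:
        fh.write("drug_id\tdrug_name\ttarget\n")
        for row in sorted(catalog_rows):
            fh.write("\t".join(row) + "\n")

    # --- instances ---------------------------------------------------------
    meta_rows = []
    z = pd.DataFrame(0.0, index=all_genes, columns=[])
    cell_lines = list(spec.cell_lines)
    for i, d in enumerate(drug_ids):
        for j in range(spec.n_instances_per_drug):
            iid = f"{d}_I{j}"
            meta_rows.append(
                {
                    "instance_id": iid,
                    "drug_id": d,
                    "cell_line": cell_lines[(i + j) % len(cell_lines)],
                    "time_h": spec.time_h,
                    "dose": spec.dose,
                }
            )
            col = np.zeros(len(all_genes))
            if spec.noise_sd:
                col += rng.normal(0.0, spec.noise_sd, size=len(all_genes))
            marker_mask = np.isin(all_genes, markers[d])
            col[marker_mask] += _MARKER_Z
            z[iid] = col
    z.index.name = "gene"
    z.to_csv(out / "instance_zscores.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(meta_rows).to_csv(out / "instance_metadata.tsv", sep="\t", index=False, float_format="%.6g")

    # --- screening ---------------------------------------------------------
    # Screens have a small strongly-suppressed tail against a large inactive
    # bulk; the mean - 1.5 SD rule presumes that shape. Planted-active drugs
    # (f >= active_cutoff_fraction) get growth rates near zero or below,
    # inactive catalog drugs sit with the background bulk near 80.
    screen_rows: list[tuple[str, float]] = []
    for d, f in zip(drug_ids, fractions):
        if f >= spec.active_cutoff_fraction:
            rate = 30.0 - 60.0 * f
        else:
            rate = 78.0 + 4.0 * f
        if spec.noise_sd:
            rate += rng.normal(0.0, 5.0 * spec.noise_sd)
        screen_rows.append((drug_names[d], rate))
    for i in range(spec.n_screen_background):
        screen_rows.append((f"Screened{i:02d}", float(rng.normal(80.0, 4.0))))
    with open(out / "screening.tsv", "w") as fh:
        fh.write("drug_name\tgrowth_rate\n")
        for name, rate in screen_rows:
            fh.write(f"{name}\t{rate:.6g}\n")

    truth = GroundTruth(
        activated_tfs=frozenset(planted),
        upregulated_targets=frozenset(upreg),
        pnet_nodes=frozenset(pnet_nodes),
        overlap_fraction=dict(zip(drug_ids, fractions)),
        expected_score={d: counts[d] / size for d in drug_ids},
        active_drugs=frozenset(
            drug_names[d]
            for d, f in zip(drug_ids, fractions)
            if f >= spec.active_cutoff_fraction
        ),
        drug_names=drug_names,
        case_ids=truth_case,
        control_ids=truth_ctrl,
    )

    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("drug_id\tdrug_name\toverlap_fraction\texpected_score\tactive\n")
        for d in drug_ids:
            fh.write(
                f"{d}\t{drug_names[d]}\t{truth.overlap_fraction[d]:.6g}"
                f"\t{truth.expected_score[d]:.6g}"
                f"\t{int(drug_names[d] in truth.active_drugs)}\n"
            )

    # a ready-to-run config so `run-all --config <dir>/config.yaml` works
    ks = sorted({max(1, spec.n_drugs // 3), max(1, spec.n_drugs // 2), spec.n_drugs})
    config = {
        "expression": "expression.tsv",
        "case_samples": truth_case,
        "control_samples": truth_ctrl,
        "interactome": "interactome.tsv",
        "interactome_dialect": "two_column",
        "tf_targets": "tf_targets.tsv",
        "disease_genes": "disease_genes.txt",
        "drug_catalog": "drug_catalog.tsv",
        "instance_matrix": "instance_zscores.tsv",
        "instance_metadata": "instance_metadata.tsv",
        "screening": "screening.tsv",
        "thresholds": {"tf_activation": 2.0, "upregulation": 2.0, "zscore": 2.0},
        "filter": {"time_h": spec.time_h, "dose": spec.dose, "exclude_cell_line": None},
        "tie_break": "lexicographic",
        "ks": ks,
        "k_sd": 1.5,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return truth
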