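"""Synthetic inputs with planted ground truth for every pipeline stage.

Real studies of this kind consume database exports (compound ADME tables,
per-database target lists, scored disease-gene tables, STRING edge exports,
GO/KEGG term collections) and a quantified serum-metabolite matrix, none of
which are redistributable.  The generators here emulate each of those inputs
and record what was planted, so that every downstream stage can be tested for
recovery of known truth:

* a compound library in which a chosen fraction passes the OB/DL thresholds;
* a PPI network with a planted high-confidence clique (the hub module);
* an annotation collection containing one term that exactly matches a planted
  gene set;
* a three-group (control / model / treatment) intensity matrix with planted
  differential metabolites, a subset of which are *reversed* — shifted one
  way in the disease model and the opposite way under treatment.

All generators are pure functions of their arguments including the seed.  A
scenario-level seed fans out to per-generator child seeds by the fixed
offsets in :data:`SEED_OFFSETS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import AnnotationCollection, Term
from .metabolomics import IntensityMatrix
from .targets import CompoundRecord, DiseaseTargetRecord, TargetSet

__all__ = [
    "SEED_OFFSETS",
    "SyntheticGroundTruth",
    "gen_compound_library",
    "gen_ppi",
    "gen_metabolomics",
    "gen_annotations",
    "Scenario",
    "gen_scenario",
]

_SEED_MOD = 2**31 - 1

#: Fixed child-seed offsets from the scenario seed, one per generator.
SEED_OFFSETS = {
    "compounds": 11,
    "sources": 23,
    "disease": 37,
    "ppi": 51,
    "mapping": 67,
    "annotations": 83,
    "metabolomics": 101,
    "links": 127,
}

HERBS = ("herb1", "herb2", "herb3", "herb4", "herb5")


def _child_seed(seed: int, name: str) -> int:
    return (int(seed) + SEED_OFFSETS[name]) % _SEED_MOD


@dataclass
class SyntheticGroundTruth:
    """What was planted, for checking recovery downstream.

    ``differential_metabolites`` maps a comparison name
    (``model_vs_control`` / ``treatment_vs_model``) to the planted ids;
    ``directions`` maps the same comparisons to per-metabolite signs of the
    planted shift.  Reversed metabolites belong to both comparisons with
    opposite signs.
    """

    seed: int
    active_compound_ids: set[str] = field(default_factory=set)
    hub_module_nodes: set[str] = field(default_factory=set)
    common_targets: set[str] = field(default_factory=set)
    enriched_term_ids: set[str] = field(default_factory=set)
    differential_metabolites: dict[str, set[str]] = field(default_factory=dict)
    reversed_metabolites: set[str] = field(default_factory=set)
    directions: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        diffs = self.differential_metabolites
        if diffs:
            for comparison, planted in diffs.items():
                if not self.reversed_metabolites <= planted:
                    raise ValueError(
                        f"reversed metabolites must be planted in {comparison!r}"
                    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "active_compound_ids": sorted(self.active_compound_ids),
            "hub_module_nodes": sorted(self.hub_module_nodes),
            "common_targets": sorted(self.common_targets),
            "enriched_term_ids": sorted(self.enriched_term_ids),
            "differential_metabolites": {
                k: sorted(v) for k, v in sorted(self.differential_metabolites.items())
            },
            "reversed_metabolites": sorted(self.reversed_metabolites),
            "directions": {
                k: dict(sorted(v.items())) for k, v in sorted(self.directions.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            seed=raw["seed"],
            active_compound_ids=set(raw["active_compound_ids"]),
            hub_module_nodes=set(raw["hub_module_nodes"]),
            common_targets=set(raw.get("common_targets", [])),
            enriched_term_ids=set(raw["enriched_term_ids"]),
            differential_metabolites={
                k: set(v) for k, v in raw["differential_metabolites"].items()
            },
            reversed_metabolites=set(raw["reversed_metabolites"]),
            directions={
                k: {m: int(d) for m, d in v.items()}
                for k, v in raw.get("directions", {}).items()
            },
        )


# ---------------------------------------------------------------------------
# Compound library
# ---------------------------------------------------------------------------

def gen_compound_library(
    n: int, frac_active: float, seed: int
) -> tuple[list[CompoundRecord], SyntheticGroundTruth]:
    """Compound table in which exactly round(n * frac_active) pass OB/DL.

    Active compounds draw OB uniformly in [30, 100] and DL in [0.18, 1];
    inactive ones fail on a randomly chosen axis (OB, DL or both), drawn
    uniformly below the threshold on the failing axis so boundary behaviour
    is exercised.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= frac_active <= 1.0:
        raise ValueError("frac_active must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_active = int(round(n * frac_active))
    flags = np.zeros(n, dtype=bool)
    flags[:n_active] = True
    rng.shuffle(flags)
    compounds: list[CompoundRecord] = []
    active_ids: set[str] = set()
    for i, active in enumerate(flags):
        cid = f"C{i + 1:04d}"
        if active:
            ob = float(rng.uniform(30.0, 100.0))
            dl = float(rng.uniform(0.18, 1.0))
            active_ids.add(cid)
        else:
            axis = rng.choice(["ob", "dl", "both"])
            ob_fail = float(rng.uniform(0.0, 29.99))
            dl_fail = float(rng.uniform(0.0, 0.1799))
            if axis == "ob":
                ob, dl = ob_fail, float(rng.uniform(0.0, 1.0))
            elif axis == "dl":
                ob, dl = float(rng.uniform(0.0, 100.0)), dl_fail
            else:
                ob, dl = ob_fail, dl_fail
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                name=f"compound-{i + 1}",
                ob=ob,
                dl=dl,
                herb=HERBS[i % len(HERBS)],
            )
        )
    truth = SyntheticGroundTruth(seed=int(seed), active_compound_ids=active_ids)
    return compounds, truth


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def gen_ppi(
    n_nodes: int,
    model: str = "erdos_renyi",
    density_param: float = 0.05,
    planted_clique: int = 0,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Random PPI graph with a planted high-confidence clique.

    Background edge scores are uniform in [0, 1]; clique edges score in
    [0.9, 1] so the module survives a 0.7 confidence filter intact.  The
    clique occupies the first ``planted_clique`` labels.  Returns the graph
    and the clique node list.
    """
    if n_nodes < 0 or planted_clique < 0 or planted_clique > n_nodes:
        raise ValueError("need n_nodes >= planted_clique >= 0")
    if labels is None:
        labels = [f"G{i + 1:04d}" for i in range(n_nodes)]
    elif len(labels) != n_nodes:
        raise ValueError("labels length must equal n_nodes")
    labels = [str(x) for x in labels]
    rng = np.random.default_rng(seed)
    if model == "erdos_renyi":
        base = nx.gnp_random_graph(n_nodes, density_param, seed=int(seed))
    elif model == "scale_free":
        m = max(1, int(round(density_param)))
        base = (
            nx.barabasi_albert_graph(n_nodes, m, seed=int(seed))
            if n_nodes > m
            else nx.empty_graph(n_nodes)
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for u, v in sorted(base.edges()):
        g.add_edge(labels[u], labels[v], score=float(rng.uniform(0.0, 1.0)))
    clique = labels[:planted_clique]
    for i in range(planted_clique):
        for j in range(i + 1, planted_clique):
            g.add_edge(clique[i], clique[j], score=float(rng.uniform(0.9, 1.0)))
    return g, list(clique)


# ---------------------------------------------------------------------------
# Metabolomics matrix
# ---------------------------------------------------------------------------

def gen_metabolomics(
    n_per_group: int = 10,
    n_metabolites: int = 100,
    n_diff_mc: int = 10,
    n_diff_mt: int = 10,
    n_reversed: int = 4,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[IntensityMatrix, SyntheticGroundTruth]:
    """Three-group intensity matrix with planted differential metabolites.

    Log-intensities are ``baseline_m + shift + noise`` with per-metabolite
    baselines N(0, 1), noise N(0, noise_sd) and planted shifts of
    ``effect_size * noise_sd``; intensities are the exponential (log-normal).
    Model-vs-control metabolites shift the model group away from control;
    treatment-vs-model metabolites shift the treatment group away from the
    model level.  Reversed metabolites carry both shifts with opposite
    signs, so treatment moves them back toward the control level.  The two
    planted sets overlap exactly in the reversed metabolites.
    """
    if n_per_group < 1 or n_metabolites < 0 or noise_sd <= 0:
        raise ValueError("need n_per_group >= 1, n_metabolites >= 0, noise_sd > 0")
    if min(n_diff_mc, n_diff_mt) < 0 or n_reversed < 0:
        raise ValueError("planted counts must be >= 0")
    if n_reversed > min(n_diff_mc, n_diff_mt):
        raise ValueError("n_reversed cannot exceed either differential count")
    n_planted = n_diff_mc + n_diff_mt - n_reversed
    if n_planted > n_metabolites:
        raise ValueError("more planted metabolites than metabolites")
    rng = np.random.default_rng(seed)
    mets = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    chosen = (
        [str(m) for m in rng.choice(mets, size=n_planted, replace=False)]
        if n_planted
        else []
    )
    reversed_ids = chosen[:n_reversed]
    mc_only = chosen[n_reversed:n_diff_mc]
    mt_only = chosen[n_diff_mc:]
    diff_mc = set(reversed_ids) | set(mc_only)
    diff_mt = set(reversed_ids) | set(mt_only)

    delta = effect_size * noise_sd
    dir_mc = {m: int(rng.choice([-1, 1])) for m in sorted(diff_mc)}
    dir_mt = {m: -dir_mc[m] for m in reversed_ids}
    dir_mt.update({m: int(rng.choice([-1, 1])) for m in sorted(mt_only)})

    baseline = rng.normal(0.0, 1.0, size=n_metabolites)
    shift = {g: np.zeros(n_metabolites) for g in ("control", "model", "treatment")}
    idx = {m: i for i, m in enumerate(mets)}
    for m in diff_mc:  # model displaced from control
        shift["model"][idx[m]] += dir_mc[m] * delta
        shift["treatment"][idx[m]] += dir_mc[m] * delta  # treatment starts at model level
    for m in diff_mt:  # treatment displaced from model
        shift["treatment"][idx[m]] += dir_mt[m] * delta

    rows, groups, samples = [], [], []
    for g in ("control", "model", "treatment"):
        for k in range(n_per_group):
            noise = rng.normal(0.0, noise_sd, size=n_metabolites)
            rows.append(np.exp(baseline + shift[g] + noise))
            samples.append(f"{g}_{k + 1:02d}")
            groups.append(g)
    matrix = IntensityMatrix(
        pd.DataFrame(rows, index=pd.Index(samples, name="sample"), columns=mets),
        pd.Series(groups, index=samples, name="group"),
    )
    truth = SyntheticGroundTruth(
        seed=int(seed),
        differential_metabolites={
            "model_vs_control": diff_mc,
            "treatment_vs_model": diff_mt,
        },
        reversed_metabolites=set(reversed_ids),
        directions={"model_vs_control": dir_mc, "treatment_vs_model": dir_mt},
    )
    truth.validate()
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotation collection
# ---------------------------------------------------------------------------

def gen_annotations(
    n_terms: int,
    universe: Sequence[str],
    size_range: tuple[int, int] = (5, 25),
    planted_term_genes: Sequence[str] = (),
    seed: int = 0,
    planted_category: str = "pathway",
) -> AnnotationCollection:
    """Random term-gene collection; term ``T0000`` equals the planted set.

    Categories cycle through BP / CC / MF / pathway for the random terms.
    """
    uni = sorted({str(g) for g in universe})
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(uni):
        raise ValueError(f"size_range must lie within [1, {len(uni)}]")
    planted = {str(g) for g in planted_term_genes}
    if not planted <= set(uni):
        raise ValueError("planted term genes must lie inside the universe")
    rng = np.random.default_rng(seed)
    coll = AnnotationCollection()
    categories = ("BP", "CC", "MF", "pathway")
    start = 0
    if planted:
        coll.add(
            Term(
                term_id="T0000",
                name="planted module",
                category=planted_category,
                genes=set(planted),
            )
        )
        start = 1
    for i in range(start, n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = set(rng.choice(uni, size=size, replace=False))
        coll.add(
            Term(
                term_id=f"T{i:04d}",
                name=f"term {i:04d}",
                category=categories[i % len(categories)],
                genes=genes,
            )
        )
    return coll


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Every input the end-to-end pipeline consumes, plus the planted truth."""

    compounds: list[CompoundRecord]
    source_target_sets: list[TargetSet]
    disease_records: list[DiseaseTargetRecord]
    ppi: nx.Graph
    compound_target_mapping: list[tuple[str, str]]
    annotations: AnnotationCollection
    intensities: IntensityMatrix
    protein_links: list[tuple[str, str]]  # (biomarker metabolite, protein)
    pathway_links: list[tuple[str, str]]  # (biomarker metabolite, pathway)
    truth: SyntheticGroundTruth

    def write(self, directory: str | Path) -> dict[str, Path]:
        from .targets import write_compounds_tsv, write_target_list

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["compounds"] = d / "compounds.tsv"
        write_compounds_tsv(self.compounds, paths["compounds"])
        for ts in self.source_target_sets:
            key = f"targets_{ts.label}"
            paths[key] = d / f"{key}.txt"
            write_target_list(ts, paths[key])
        paths["disease_targets"] = d / "disease_targets.tsv"
        pd.DataFrame(
            [(r.symbol, r.relevance) for r in self.disease_records],
            columns=["symbol", "relevance"],
        ).to_csv(paths["disease_targets"], sep="\t", index=False)
        paths["ppi_edges"] = d / "ppi_edges.tsv"
        pd.DataFrame(
            [
                (u, v, data["score"])
                for u, v, data in sorted(self.ppi.edges(data=True), key=str)
            ],
            columns=["node1", "node2", "combined_score"],
        ).to_csv(paths["ppi_edges"], sep="\t", index=False)
        paths["compound_targets"] = d / "compound_targets.tsv"
        pd.DataFrame(
            sorted(self.compound_target_mapping), columns=["compound_id", "symbol"]
        ).to_csv(paths["compound_targets"], sep="\t", index=False)
        paths["annotations"] = d / "annotations.gmt"
        self.annotations.to_gmt(paths["annotations"])
        paths["intensities"] = d / "intensities.tsv"
        self.intensities.to_tsv(paths["intensities"])
        paths["protein_links"] = d / "biomarker_proteins.tsv"
        pd.DataFrame(
            sorted(self.protein_links), columns=["metabolite_id", "protein"]
        ).to_csv(paths["protein_links"], sep="\t", index=False)
        paths["pathway_links"] = d / "biomarker_pathways.tsv"
        pd.DataFrame(
            sorted(self.pathway_links), columns=["metabolite_id", "pathway"]
        ).to_csv(paths["pathway_links"], sep="\t", index=False)
        paths["ground_truth"] = d / "ground_truth.json"
        self.truth.to_json(paths["ground_truth"])
        return paths


def gen_scenario(
    seed: int = 0,
    n_compounds: int = 210,
    n_active: int = 30,
    n_universe: int = 300,
    n_drug_targets: int = 120,
    n_disease_extra: int = 140,
    n_common: int = 60,
    clique_size: int = 8,
    ppi_density: float = 0.03,
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (5, 25),
    n_per_group: int = 10,
    n_metabolites: int = 100,
    n_diff_mc: int = 10,
    n_diff_mt: int = 10,
    n_reversed: int = 4,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    n_link_proteins: int = 24,
    n_link_pathways: int = 18,
) -> Scenario:
    """Generate a coherent end-to-end study with planted truth at every stage.

    The default shape echoes the reporting grammar of published herbal
    network-pharmacology studies (a 210-compound library of which 30 pass
    ADME, five target databases, a disease-target table screened at the
    median, a confidence-scored PPI network with a hub module, and a
    three-group metabolomics matrix with four reversed biomarkers) at desk
    scale.
    """
    if n_common > n_drug_targets or clique_size > n_common:
        raise ValueError("need clique_size <= n_common <= n_drug_targets")
    if n_drug_targets + n_disease_extra > n_universe:
        raise ValueError("universe too small for drug + disease-only targets")

    compounds, ctruth = gen_compound_library(
        n_compounds, n_active / n_compounds if n_compounds else 0.0,
        _child_seed(seed, "compounds"),
    )
    active_ids = sorted(ctruth.active_compound_ids)

    universe = [f"GS{i + 1:04d}" for i in range(n_universe)]
    rng_src = np.random.default_rng(_child_seed(seed, "sources"))
    drug_union = sorted(rng_src.choice(universe, size=n_drug_targets, replace=False))
    source_names = ["db1", "db2", "db3", "db4", "db5"]
    source_sets: list[TargetSet] = []
    assignment = rng_src.integers(0, len(source_names), size=n_drug_targets)
    for s_idx, name in enumerate(source_names):
        members = {drug_union[i] for i in range(n_drug_targets) if assignment[i] == s_idx}
        extra = rng_src.choice(drug_union, size=max(5, n_drug_targets // 6), replace=False)
        members |= set(extra)
        source_sets.append(TargetSet.from_symbols(name, members))

    # Disease table: the planted common set C gets the top relevance scores so
    # the median screen retains all of C; the remaining disease genes are
    # disjoint from the drug targets, making the common-target intersection
    # exactly C by construction.
    rng_dis = np.random.default_rng(_child_seed(seed, "disease"))
    common = sorted(rng_dis.choice(drug_union, size=n_common, replace=False))
    non_drug = sorted(set(universe) - set(drug_union))
    disease_only = sorted(rng_dis.choice(non_drug, size=n_disease_extra, replace=False))
    n_disease = n_common + n_disease_extra
    scores = np.sort(rng_dis.exponential(scale=1.0, size=n_disease))[::-1]
    disease_records = [
        DiseaseTargetRecord(sym, float(s))
        for sym, s in zip(
            list(rng_dis.permutation(common)) + list(rng_dis.permutation(disease_only)),
            scores,
        )
    ]

    clique_nodes = sorted(rng_dis.choice(common, size=clique_size, replace=False))
    other_common = [c for c in common if c not in clique_nodes]
    ppi, clique = gen_ppi(
        n_nodes=n_common,
        model="erdos_renyi",
        density_param=ppi_density,
        planted_clique=clique_size,
        seed=_child_seed(seed, "ppi"),
        labels=clique_nodes + other_common,
    )

    rng_map = np.random.default_rng(_child_seed(seed, "mapping"))
    mapping: list[tuple[str, str]] = []
    for cid in active_ids:
        n_links = int(rng_map.integers(3, 9))
        n_clique = int(rng_map.integers(1, min(n_links, clique_size) + 1))
        picks = set(rng_map.choice(clique, size=n_clique, replace=False))
        picks |= set(rng_map.choice(common, size=n_links - n_clique, replace=False))
        mapping.extend((cid, sym) for sym in sorted(picks))
    # edges that must be filtered out downstream: inactive compounds and
    # targets outside the hub set
    inactive = [c.compound_id for c in compounds if c.compound_id not in ctruth.active_compound_ids]
    for cid in inactive[:5]:
        mapping.append((cid, clique[0]))
    for cid in active_ids[:3]:
        mapping.append((cid, disease_only[0]))

    annotations = gen_annotations(
        n_terms=n_terms,
        universe=universe,
        size_range=term_size_range,
        planted_term_genes=clique,
        seed=_child_seed(seed, "annotations"),
    )

    intensities, mtruth = gen_metabolomics(
        n_per_group=n_per_group,
        n_metabolites=n_metabolites,
        n_diff_mc=n_diff_mc,
        n_diff_mt=n_diff_mt,
        n_reversed=n_reversed,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=_child_seed(seed, "metabolomics"),
    )

    rng_link = np.random.default_rng(_child_seed(seed, "links"))
    reversed_ids = sorted(mtruth.reversed_metabolites)
    protein_pool = sorted(rng_link.choice(common, size=n_link_proteins, replace=False))
    pathway_pool = [f"pathway_{i + 1:02d}" for i in range(n_link_pathways)]
    protein_links: list[tuple[str, str]] = []
    pathway_links: list[tuple[str, str]] = []
    if reversed_ids:
        # every protein/pathway linked at least once; the first biomarker is
        # the designated high-degree core biomarker
        for j, prot in enumerate(protein_pool):
            bm = reversed_ids[0] if j % 2 == 0 else reversed_ids[j % len(reversed_ids)]
            protein_links.append((bm, prot))
        for j, pw in enumerate(pathway_pool):
            bm = reversed_ids[0] if j % 2 == 0 else reversed_ids[j % len(reversed_ids)]
            pathway_links.append((bm, pw))

    truth = SyntheticGroundTruth(
        seed=int(seed),
        active_compound_ids=ctruth.active_compound_ids,
        hub_module_nodes=set(clique),
        common_targets=set(common),
        enriched_term_ids={"T0000"},
        differential_metabolites=mtruth.differential_metabolites,
        reversed_metabolites=mtruth.reversed_metabolites,
        directions=mtruth.directions,
    )
    truth.validate()
    return Scenario(
        compounds=compounds,
        source_target_sets=source_sets,
        disease_records=disease_records,
        ppi=ppi,
        compound_target_mapping=mapping,
        annotations=annotations,
        intensities=intensities,
        protein_links=protein_links,
        pathway_links=pathway_links,
        truth=truth,
    )
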