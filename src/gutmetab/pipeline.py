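"""End-to-end pipeline: simulate -> assign -> diversity -> metabolites ->
network -> integrate, with a hash manifest and stage skipping.

Each stage declares its input and output files. A stage is re-executed when
any declared output is missing or any declared input hash differs from the
manifest of the previous run; otherwise it is skipped, so deleting an
intermediate file re-runs exactly that stage and its dependents. Identical
configuration and seed give identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as dv
from . import features as ft
from . import integration as ig
from . import network as nw
from . import taxonomy as tx
from .simulate import SimulationDesign, simulate_study

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, file-serializable configuration for one pipeline run.

    Threshold defaults follow the analysis conventions this pipeline
    reproduces: fragment tolerance 0.005 Da, cosine 0.7, >= 4 MS2 matches,
    association cutoff 0.65, blank ratio 3, 10 ppm moiety tolerance.
    """

    out_dir: str = "run"
    seed: int = 0
    n_conditions: int = 5
    n_replicates: int = 5
    n_ref_taxa: int = 12
    n_asvs: int = 30
    n_features: int = 120
    moiety: str = "C3H6NO3S"
    moieties: list[str] = field(default_factory=lambda: ["C3H6NO3S", "H2"])
    rank: str = "genus"
    top_k: int = 9
    fragment_tol: float = 0.005
    cosine_min: float = 0.7
    min_matches: int = 4
    association_cutoff: float = 0.65
    blank_ratio: float = 3.0
    ppm_tol: float = 10.0
    n_components: int = 2
    keep_x: int = 10
    keep_y: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.cosine_min <= 1:
            raise ValueError("cosine_min must lie in (0, 1]")
        if not 0 < self.association_cutoff <= 1:
            raise ValueError("association_cutoff must lie in (0, 1]")
        if self.fragment_tol <= 0 or self.ppm_tol <= 0 or self.blank_ratio < 0:
            raise ValueError("tolerances must be positive")
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")
        if self.rank not in tx.RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def design(self) -> SimulationDesign:
        return SimulationDesign(
            n_conditions=self.n_conditions, n_replicates=self.n_replicates,
            n_ref_taxa=self.n_ref_taxa, n_asvs=self.n_asvs,
            n_features=self.n_features, seed=self.seed,
        )

    @property
    def network_params(self) -> nw.NetworkParams:
        return nw.NetworkParams(self.fragment_tol, self.cosine_min, self.min_matches)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------- stages ---

def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    simulate_study(cfg.design, cfg.moiety).write(out)


def _stage_assign(cfg: RunConfig, out: Path) -> None:
    ref = tx.ReferenceDB.from_files(out / "reference.fasta", out / "taxonomy.tsv",
                                    out / "copy_numbers.tsv")
    from Bio import SeqIO

    asvs = {r.id: str(r.seq) for r in SeqIO.parse(str(out / "asvs.fasta"), "fasta")}
    counts = pd.read_csv(out / "asv_counts.tsv", sep="\t", index_col=0)
    assignments = tx.assign_all(asvs, ref)
    tx.assignments_to_frame(assignments).to_csv(out / "assignments.tsv", sep="\t")
    for rank in ("phylum", cfg.rank):
        agg = tx.aggregate_at_rank(assignments, counts, rank)
        table = tx.copy_number_normalize(agg, ref.copy_numbers, rank)
        table.matrix.rename_axis(rank).to_csv(out / f"abundance_{rank}.tsv", sep="\t")


def _stage_diversity(cfg: RunConfig, out: Path) -> None:
    phylum = pd.read_csv(out / "abundance_phylum.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out / "microbiome_metadata.csv", index_col=0)
    alpha = dv.alpha_diversity_table(phylum)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    dist = dv.bray_curtis(phylum)
    dist.to_csv(out / "braycurtis.tsv", sep="\t")
    ord_res = dv.pcoa(dist)
    ord_res.coordinates.rename_axis("sample").to_csv(out / "pcoa.tsv", sep="\t")
    comp = dv.top_taxa_composition(phylum, meta["condition"], cfg.top_k)
    comp.rename_axis("taxon").to_csv(out / "composition.tsv", sep="\t")
    res = dv.group_tests(alpha["shannon"], meta["condition"])
    rows = [{"comparison": "omnibus", "statistic": res.omnibus_statistic,
             "p_value": res.omnibus_p, "threshold": res.per_comparison_threshold}]
    rows += [{"comparison": f"{a} vs {b}", "statistic": r.statistic,
              "p_value": r.p_value, "threshold": res.per_comparison_threshold}
             for (a, b), r in res.pairwise.items()]
    pd.DataFrame(rows).to_csv(out / "diversity_tests.tsv", sep="\t", index=False)


def _stage_metabolites(cfg: RunConfig, out: Path) -> None:
    table = ft.FeatureTable.from_csv(out / "features.csv", out / "feature_metadata.csv")
    filtered = ft.blank_filter(table, cfg.blank_ratio)
    filtered.to_csv(out / "features_filtered.csv")
    fc = ft.fold_change(filtered)
    fc.table.to_csv(out / "fold_changes.tsv", sep="\t")
    scores, evr = ft.pca_scores(filtered)
    scores.rename_axis("sample").to_csv(out / "pca_scores.tsv", sep="\t")
    pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(evr))],
                  "explained_variance_ratio": evr}).to_csv(
        out / "pca_variance.tsv", sep="\t", index=False)


def _stage_network(cfg: RunConfig, out: Path) -> None:
    spectra = nw.read_mgf(out / "spectra.mgf")
    filtered_ids = set(pd.read_csv(out / "features_filtered.csv", index_col=0).index.astype(str))
    spectra = [s for s in spectra if s.feature_id in filtered_ids]
    params = cfg.network_params
    edges = nw.build_network(spectra, params)
    nw.edges_to_frame(edges).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    fc_frame = pd.read_csv(out / "fold_changes.tsv", sep="\t", index_col=0)
    fc_frame.index = fc_frame.index.astype(str)
    fc = ft.FoldChangeResult(table=fc_frame)
    cands = nw.find_biotransformation_candidates(
        spectra, cfg.moieties, cfg.ppm_tol, fc, params, edges=edges)
    pd.DataFrame(
        [{"parent": c.parent_id, "product": c.product_id, "delta_mass": c.delta_mass,
          "moiety": c.moiety, "variant": c.variant, "ppm_error": c.ppm_error,
          "direction_consistent": c.direction_consistent} for c in cands],
        columns=["parent", "product", "delta_mass", "moiety", "variant",
                 "ppm_error", "direction_consistent"],
    ).to_csv(out / "biotransformation_candidates.tsv", sep="\t", index=False)
    consistent = [c for c in cands if c.direction_consistent]
    if consistent:
        by_id = {s.feature_id: s for s in spectra}
        c = consistent[0]
        nw.mirror_data(by_id[c.parent_id], by_id[c.product_id], params).to_csv(
            out / "mirror_plot.csv", index=False)
    import networkx as nx

    nx.write_graphml(nw.to_networkx(spectra, edges), out / "network.graphml")


def _stage_integrate(cfg: RunConfig, out: Path) -> None:
    abundance = pd.read_csv(out / f"abundance_{cfg.rank}.tsv", sep="\t", index_col=0)
    feats = pd.read_csv(out / "features_filtered.csv", index_col=0)
    meta = pd.read_csv(out / "feature_metadata.csv", index_col=0)
    inoc = meta[meta["role"] == "inoculated"]
    # align metabolome columns to microbiome samples via the metadata mapping
    pairs = [(m, s) for s, m in inoc["microbiome_sample"].items() if m in abundance.columns]
    micro_samples = [m for m, _ in pairs]
    met_samples = [s for _, s in pairs]
    x = ig.clr_transform(abundance[micro_samples], pseudocount=1e-6).T
    y = ig.clr_transform(feats.loc[:, met_samples], pseudocount=1.0).T
    y.index = micro_samples
    model = ig.spls_two_block(x, y, cfg.n_components,
                              min(cfg.keep_x, x.shape[1]), min(cfg.keep_y, y.shape[1]))
    model.x_loadings.rename_axis("taxon").to_csv(out / "x_loadings.tsv", sep="\t")
    model.y_loadings.rename_axis("feature").to_csv(out / "y_loadings.tsv", sep="\t")
    model.x_variates.rename_axis("sample").to_csv(out / "x_variates.tsv", sep="\t")
    model.y_variates.rename_axis("sample").to_csv(out / "y_variates.tsv", sep="\t")
    net = ig.association_network(model, x, y, cfg.association_cutoff)
    net.edges.to_csv(out / "association_edges.tsv", sep="\t", index=False)
    groups = [m.rsplit("__", 1)[0] for m in micro_samples]
    f_stat, p = ig.component_group_anova(model.x_variates.iloc[:, 0].to_numpy(), groups)
    pd.DataFrame([{"component": "comp1", "F": f_stat, "p_value": p}]).to_csv(
        out / "integration_anova.tsv", sep="\t", index=False)


def STAGES(cfg: RunConfig) -> list[tuple[str, object, list[str], list[str]]]:
    """Stage plan: (name, function, input files, output files) per stage,
    with paths relative to the run directory."""
    assign_out = ["assignments.tsv", "abundance_phylum.tsv"]
    if cfg.rank != "phylum":
        assign_out.append(f"abundance_{cfg.rank}.tsv")
    return [
        ("simulate", _stage_simulate, [],
         ["reference.fasta", "taxonomy.tsv", "copy_numbers.tsv", "asvs.fasta",
          "asv_counts.tsv", "microbiome_metadata.csv", "features.csv",
          "feature_metadata.csv", "spectra.mgf", "ground_truth.json"]),
        ("assign", _stage_assign,
         ["reference.fasta", "taxonomy.tsv", "copy_numbers.tsv", "asvs.fasta",
          "asv_counts.tsv"],
         assign_out),
        ("diversity", _stage_diversity,
         ["abundance_phylum.tsv", "microbiome_metadata.csv"],
         ["alpha_diversity.tsv", "braycurtis.tsv", "pcoa.tsv", "composition.tsv",
          "diversity_tests.tsv"]),
        ("metabolites", _stage_metabolites,
         ["features.csv", "feature_metadata.csv"],
         ["features_filtered.csv", "fold_changes.tsv", "pca_scores.tsv",
          "pca_variance.tsv"]),
        ("network", _stage_network,
         ["spectra.mgf", "features_filtered.csv", "fold_changes.tsv"],
         ["network_edges.tsv", "biotransformation_candidates.tsv", "network.graphml"]),
        ("integrate", _stage_integrate,
         [f"abundance_{cfg.rank}.tsv", "features_filtered.csv", "feature_metadata.csv"],
         ["x_loadings.tsv", "y_loadings.tsv", "x_variates.tsv", "y_variates.tsv",
          "association_edges.tsv", "integration_anova.tsv"]),
    ]


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Run all stages in dependency order; returns the manifest.

    A stage is skipped when its outputs all exist and its input hashes match
    the stored manifest; ``force=True`` re-runs everything.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old = {}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text()).get("stages", {})
    manifest: dict = {"config": asdict(config), "stages": {}}
    for name, func, inputs, outputs in STAGES(config):
        in_paths = [out / f for f in inputs]
        missing_inputs = [str(p) for p in in_paths if not p.exists()]
        if missing_inputs:
            raise RuntimeError(f"stage {name!r} failed: missing inputs {missing_inputs}")
        in_hashes = {f: _sha256(out / f) for f in inputs}
        prev = old.get(name)
        out_paths = [out / f for f in outputs]
        can_skip = (
            prev is not None
            and prev.get("inputs") == in_hashes
            and all(p.exists() for p in out_paths)
            and all(_sha256(out / f) == h for f, h in prev.get("outputs", {}).items())
        )
        if can_skip:
            entry = dict(prev)
            entry["skipped"] = True
            manifest["stages"][name] = entry
            logger.info("stage %s: up to date, skipped", name)
            continue
        t0 = time.perf_counter()
        try:
            func(config, out)
        except Exception as exc:
            for p in out_paths:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".incomplete"))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "inputs": in_hashes,
            "outputs": {f: _sha256(out / f) for f in outputs},
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "skipped": False,
        }
        logger.info("stage %s: done in %.2fs", name, manifest["stages"][name]["wall_time_s"])
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
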