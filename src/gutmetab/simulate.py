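"""Synthetic ex vivo study generator with planted ground truth.

Emulates the data structure of an ex vivo herb-supplementation experiment on
a pooled human fecal community: five culture conditions (control, three
herbs, one purified compound) with five technical replicates each, 16S ASVs
derived from reference sequences by point mutation, overdispersed log-normal
count profiles closed by multinomial resampling, and an LC-MS feature table
with paired crude / fecal-inoculated extracts plus blanks.

Planted structure, recorded in :class:`GroundTruth`:

* every ASV's source reference taxon (and its mutation count),
* taxa with 5-fold condition effects (differential abundance),
* a parent -> product metabolite pair whose precursor masses differ by a
  conjugated moiety (default C3H6NO3S) and whose abundances invert upon
  inoculation, with MS/MS spectra sharing fragments directly and at the
  precursor offset,
* taxon-metabolite pairs coupled through a shared per-sample latent factor,
  giving recoverable cross-block correlation.

All randomness flows through one labelled stream per artifact derived from
the master seed, so outputs are byte-identical across reruns and adding a
new output never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream
from .masses import PROTON_MASS, monoisotopic_mass
from .network import SpectrumRecord, write_mgf
from .taxonomy import RANKS, RefRecord, ReferenceDB
from .features import FeatureTable

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "SyntheticStudy",
    "generate_reference_db",
    "generate_asv_data",
    "generate_metabolomics_data",
    "simulate_study",
]

_BASES = np.array(list("ACGT"))

_PHYLA = ["Bacillota", "Bacteroidota", "Actinomycetota", "Pseudomonadota",
          "Verrucomicrobiota", "Fusobacteriota"]

#: Condition labels for the default five-condition design.
_DEFAULT_CONDITIONS = ["control", "a_absinthium", "a_annua", "a_californica", "artemisinin"]

LIBRARY_SIZE = 50_000
#: multiplicative condition effect planted on differential taxa
DIFFERENTIAL_FOLD = 5.0
#: log-scale coupling of associated taxa / features to the shared latent factor
LATENT_EFFECT = 1.2
N_DIFFERENTIAL = 4
N_ASSOCIATED = 4
N_BLANKS = 3


@dataclass(frozen=True)
class SimulationDesign:
    """Study geometry and master seed for one synthetic dataset."""

    n_conditions: int = 5
    n_replicates: int = 5
    n_ref_taxa: int = 12
    n_asvs: int = 30
    n_features: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_conditions", "n_replicates", "n_ref_taxa", "n_asvs", "n_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def conditions(self) -> list[str]:
        if self.n_conditions == len(_DEFAULT_CONDITIONS):
            return list(_DEFAULT_CONDITIONS)
        return ["control"] + [f"treatment_{i}" for i in range(1, self.n_conditions)]

    @property
    def samples(self) -> list[str]:
        return [f"{c}__r{j}" for c in self.conditions for j in range(1, self.n_replicates + 1)]


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    asv_to_taxon: dict[str, str] = field(default_factory=dict)  # ASV id -> reference id
    asv_to_genus: dict[str, str] = field(default_factory=dict)
    asv_mutations: dict[str, int] = field(default_factory=dict)
    differential_taxa: list[dict] = field(default_factory=list)  # {taxon, genus, condition, fold}
    associated_pairs: list[dict] = field(default_factory=list)  # {taxon, genus, feature}
    planted_pair: dict | None = None  # {parent, product, moiety}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(**{**self.__dict__})
        out.asv_to_taxon.update(other.asv_to_taxon)
        out.asv_to_genus.update(other.asv_to_genus)
        out.asv_mutations.update(other.asv_mutations)
        out.differential_taxa = self.differential_taxa + other.differential_taxa
        out.associated_pairs = self.associated_pairs + other.associated_pairs
        out.planted_pair = other.planted_pair or self.planted_pair
        return out


def _latent(design: SimulationDesign) -> pd.Series:
    """Shared per-sample latent factor coupling the two omic blocks."""
    rng = stream(design.seed, "latent")
    return pd.Series(rng.standard_normal(len(design.samples)), index=design.samples)


#: per-taxon substitution probability from the shared ancestral sequence;
#: gives ~78% pairwise identity between references, 16S-variable-region-like
REFERENCE_DIVERGENCE = 0.12


def generate_reference_db(n_taxa: int, seed: int) -> ReferenceDB:
    """16S-like reference database with nested 6-rank lineages.

    All sequences are homologs: each taxon derives from one random ancestral
    sequence (length drawn from 250-450 nt) by independent substitutions at
    rate `REFERENCE_DIVERGENCE` per site, as real 16S references share most
    of their gene. Per-species copy numbers are drawn uniformly from the
    integers 1-15 and averaged upward so every rank level carries the mean
    copy number of its member species.
    """
    if n_taxa < 2:
        raise ValueError("need at least two reference taxa")
    rng = stream(seed, "reference_db")
    length = int(rng.integers(250, 451))
    ancestor = _BASES[rng.integers(0, 4, size=length)]
    records = []
    species_copies: dict[str, int] = {}
    lineages = []
    for i in range(n_taxa):
        arr = ancestor.copy()
        hit = np.nonzero(rng.random(length) < REFERENCE_DIVERGENCE)[0]
        for pos in hit:
            choices = [b for b in "ACGT" if b != arr[pos]]
            arr[pos] = choices[rng.integers(0, 3)]
        seq = "".join(arr)
        lineage = {
            "phylum": _PHYLA[(i // 4) % len(_PHYLA)],
            "class": f"Class{i // 3 + 1:02d}",
            "order": f"Order{i // 2 + 1:02d}",
            "family": f"Family{i // 2 + 1:02d}",
            "genus": f"Genus{i + 1:02d}",
            "species": f"Species{i + 1:02d}",
        }
        records.append(RefRecord(f"REF_{i+1:03d}", seq, lineage))
        species_copies[lineage["species"]] = int(rng.integers(1, 16))
        lineages.append(lineage)
    copy_numbers: dict[tuple[str, str], float] = {}
    for rank in RANKS:
        names = {lin[rank] for lin in lineages}
        for name in names:
            members = [species_copies[lin["species"]] for lin in lineages if lin[rank] == name]
            copy_numbers[(rank, name)] = float(np.mean(members))
    return ReferenceDB(records, copy_numbers)


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    if k == 0:
        return seq
    arr = np.array(list(seq))
    positions = rng.choice(arr.size, size=min(k, arr.size), replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_asv_data(
    ref: ReferenceDB, design: SimulationDesign
) -> tuple[dict[str, str], pd.DataFrame, GroundTruth]:
    """ASV sequences, a count table and planted truth.

    Each ASV copies one reference with 0-10 point mutations. Expected
    abundances follow a log-normal(mu=5, sigma=1) baseline, multiplied by the
    5-fold condition effect for differential taxa and by exp(1.2 * latent)
    for latent-associated taxa, then closed to a 50,000-read library by
    multinomial resampling per sample.
    """
    if len(ref) == 0:
        raise ValueError("reference database is empty")
    rng_seq = stream(design.seed, "asv_sequences")
    rng_counts = stream(design.seed, "asv_counts")
    rng_eff = stream(design.seed, "asv_effects")
    n_taxa = len(ref)

    truth = GroundTruth()
    asv_seqs: dict[str, str] = {}
    source_idx = []
    for i in range(design.n_asvs):
        asv_id = f"ASV_{i+1:04d}"
        src = i % n_taxa
        k = int(rng_seq.integers(0, 11))
        asv_seqs[asv_id] = _mutate(ref.records[src].sequence, k, rng_seq)
        source_idx.append(src)
        truth.asv_to_taxon[asv_id] = ref.records[src].id
        truth.asv_to_genus[asv_id] = ref.records[src].lineage["genus"]
        truth.asv_mutations[asv_id] = k

    conditions = design.conditions
    non_control = [c for c in conditions if c != "control"] or conditions
    diff_idx = rng_eff.choice(n_taxa, size=min(N_DIFFERENTIAL, n_taxa), replace=False)
    remaining = np.setdiff1d(np.arange(n_taxa), diff_idx)
    pool = remaining if remaining.size >= min(N_ASSOCIATED, n_taxa) else np.arange(n_taxa)
    assoc_idx = rng_eff.choice(pool, size=min(N_ASSOCIATED, pool.size), replace=False)
    for k, t in enumerate(diff_idx):
        cond = non_control[int(rng_eff.integers(0, len(non_control)))]
        # both directions occur; at least one enrichment is always planted
        up = True if k == 0 else bool(rng_eff.integers(0, 2))
        truth.differential_taxa.append({
            "taxon": ref.records[t].id,
            "genus": ref.records[t].lineage["genus"],
            "condition": cond,
            "fold": DIFFERENTIAL_FOLD if up else 1.0 / DIFFERENTIAL_FOLD,
        })
    assoc_taxa = [ref.records[t] for t in assoc_idx]

    baseline = rng_counts.lognormal(mean=5.0, sigma=1.0, size=design.n_asvs)
    latent = _latent(design)
    diff_by_taxon = {(d["taxon"], d["condition"]): d["fold"] for d in truth.differential_taxa}
    assoc_ids = {r.id for r in assoc_taxa}

    counts = np.zeros((design.n_asvs, len(design.samples)), dtype=int)
    for s_i, sample in enumerate(design.samples):
        cond = sample.rsplit("__", 1)[0]
        expected = baseline.copy()
        for a_i, src in enumerate(source_idx):
            taxon_id = ref.records[src].id
            expected[a_i] *= diff_by_taxon.get((taxon_id, cond), 1.0)
            if taxon_id in assoc_ids:
                expected[a_i] *= float(np.exp(LATENT_EFFECT * latent[sample]))
        counts[:, s_i] = rng_counts.multinomial(LIBRARY_SIZE, expected / expected.sum())
    count_table = pd.DataFrame(counts, index=list(asv_seqs), columns=design.samples)

    # taxon-side half of the association pairs; features are filled in by the
    # metabolomics generator, which draws the same feature ids
    for j, r in enumerate(assoc_taxa):
        truth.associated_pairs.append({
            "taxon": r.id, "genus": r.lineage["genus"],
            "feature": _associated_feature_id(design, j),
        })
    return asv_seqs, count_table, truth


# --- metabolomics -----------------------------------------------------------

PARENT_FORMULA = "C15H22O5"  # artemisinin-like parent compound
PARENT_ID = "FT_00001"
PRODUCT_ID = "FT_00002"


def _associated_feature_id(design: SimulationDesign, j: int) -> str:
    # features 3.. after the planted parent/product pair
    return f"FT_{3 + j:05d}"


def metabolomics_samples(design: SimulationDesign) -> pd.DataFrame:
    """Sample sheet for the LC-MS block: paired crude/inoculated + blanks."""
    rows = []
    for cond in design.conditions:
        for j in range(1, design.n_replicates + 1):
            for role, tag in (("crude", "crude"), ("inoculated", "inoc")):
                rows.append({
                    "sample": f"{cond}__r{j}__{tag}",
                    "role": role,
                    "condition": cond,
                    "replicate": j,
                    "microbiome_sample": f"{cond}__r{j}" if role == "inoculated" else "",
                })
    for b in range(1, N_BLANKS + 1):
        rows.append({"sample": f"blank__{b}", "role": "blank", "condition": "",
                     "replicate": b, "microbiome_sample": ""})
    return pd.DataFrame(rows).set_index("sample")


def generate_metabolomics_data(
    design: SimulationDesign, moiety_formula: str = "C3H6NO3S"
) -> tuple[FeatureTable, list[SpectrumRecord], GroundTruth]:
    """LC-MS feature table, MS/MS spectra and planted truth.

    Plants a parent/product pair whose precursor masses differ by the
    monoisotopic mass of ``moiety_formula``; the parent drops at least
    4-fold upon inoculation in every replicate while the product rises
    correspondingly, and their spectra share six fragments (three direct,
    three at the precursor offset) that dominate the intensity so the pair
    passes the default networking thresholds. Latent-associated features
    track the shared latent factor in the inoculated samples. Blank columns
    sit at ~1% of sample means.
    """
    moiety_mass = monoisotopic_mass(moiety_formula)  # raises FormulaError if bad
    rng = stream(design.seed, "metabolomics")
    rng_spec = stream(design.seed, "spectra")
    meta = metabolomics_samples(design)
    samples = list(meta.index)
    n_feat = max(design.n_features, 3 + N_ASSOCIATED)

    ids = [f"FT_{i+1:05d}" for i in range(n_feat)]
    mz = rng.uniform(100.0, 1000.0, size=n_feat)
    rt = rng.uniform(0.5, 12.0, size=n_feat)
    parent_mz = monoisotopic_mass(PARENT_FORMULA) + PROTON_MASS
    mz[0], mz[1] = parent_mz, parent_mz + moiety_mass

    baseline = rng.lognormal(mean=13.0, sigma=1.2, size=n_feat)
    baseline[0], baseline[1] = 5e6, 4e5
    latent = _latent(design)

    # generic crude/inoculated shifts on a background subset (metabolic
    # turnover of herb constituents), giving the PCA its separation
    n_shift = min(20, n_feat - 3 - N_ASSOCIATED) if n_feat > 3 + N_ASSOCIATED else 0
    shift_idx = 3 + N_ASSOCIATED + np.arange(n_shift)
    shift_fold = np.where(rng.integers(0, 2, size=n_shift) == 1, 4.0, 0.25)

    inten = np.zeros((n_feat, len(samples)))
    for s_i, sample in enumerate(samples):
        role = meta.loc[sample, "role"]
        if role == "blank":
            continue
        expected = baseline.copy()
        if role == "inoculated":
            expected[0] *= float(np.clip(rng.lognormal(np.log(1 / 8), 0.2), 1 / 16, 1 / 4.5))
            expected[1] *= float(np.clip(rng.lognormal(np.log(8), 0.2), 4.5, 16))
            expected[shift_idx] *= shift_fold
            g = latent[meta.loc[sample, "microbiome_sample"]]
            for j in range(N_ASSOCIATED):
                expected[2 + j] *= float(np.exp(LATENT_EFFECT * g))
        noise = rng.lognormal(mean=0.0, sigma=0.3, size=n_feat)
        inten[:, s_i] = expected * noise
    sample_cols = [s for s in samples if meta.loc[s, "role"] != "blank"]
    sample_mean = inten[:, [samples.index(s) for s in sample_cols]].mean(axis=1)
    for s_i, sample in enumerate(samples):
        if meta.loc[sample, "role"] == "blank":
            inten[:, s_i] = 0.01 * sample_mean * rng.lognormal(0.0, 0.3, size=n_feat)

    table = FeatureTable(
        features=pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(ids, name="id")),
        intensities=pd.DataFrame(inten, index=ids, columns=samples),
        sample_meta=meta,
    )

    spectra = []
    # planted pair: six dominant shared fragments, three direct + three at
    # the precursor offset, jittered below the 0.005 Da match tolerance
    shared_mz = np.sort(rng_spec.uniform(60.0, parent_mz - 10.0, size=6))
    shared_int = rng_spec.uniform(5e5, 1e6, size=6)
    own_parent = rng_spec.uniform(50.0, parent_mz - 1.0, size=8)
    own_product = rng_spec.uniform(50.0, parent_mz - 1.0, size=8)
    low = lambda n: rng_spec.uniform(1e3, 1e4, size=n)
    jitter = lambda n: rng_spec.uniform(-0.002, 0.002, size=n)
    spectra.append(SpectrumRecord(
        PARENT_ID, parent_mz,
        np.concatenate([shared_mz, own_parent]),
        np.concatenate([shared_int, low(8)]),
    ))
    spectra.append(SpectrumRecord(
        PRODUCT_ID, parent_mz + moiety_mass,
        np.concatenate([shared_mz[:3] + jitter(3),
                        shared_mz[3:] + moiety_mass + jitter(3),
                        own_product]),
        np.concatenate([shared_int * rng_spec.lognormal(0.0, 0.05, size=6), low(8)]),
    ))
    for i in range(2, n_feat):
        n_peaks = int(rng_spec.integers(10, 31))
        pk_mz = rng_spec.uniform(50.0, max(mz[i] - 1.0, 60.0), size=n_peaks)
        pk_int = rng_spec.uniform(1e3, 1e6, size=n_peaks)
        spectra.append(SpectrumRecord(ids[i], float(mz[i]), pk_mz, pk_int))

    truth = GroundTruth(planted_pair={
        "parent": PARENT_ID, "product": PRODUCT_ID, "moiety": moiety_formula,
    })
    for j in range(N_ASSOCIATED):
        # feature-side ids; the taxon side is recorded by generate_asv_data
        assert _associated_feature_id(design, j) == ids[2 + j]
    return table, spectra, truth


@dataclass
class SyntheticStudy:
    """Everything one synthetic run produces, in memory."""

    design: SimulationDesign
    reference: ReferenceDB
    asv_sequences: dict[str, str]
    asv_counts: pd.DataFrame
    microbiome_meta: pd.DataFrame
    feature_table: FeatureTable
    spectra: list[SpectrumRecord]
    truth: GroundTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write every artifact as plain text; returns name -> path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {name: out / fname for name, fname in [
            ("reference_fasta", "reference.fasta"), ("taxonomy", "taxonomy.tsv"),
            ("copy_numbers", "copy_numbers.tsv"), ("asv_fasta", "asvs.fasta"),
            ("asv_counts", "asv_counts.tsv"), ("microbiome_metadata", "microbiome_metadata.csv"),
            ("features", "features.csv"), ("feature_metadata", "feature_metadata.csv"),
            ("spectra", "spectra.mgf"), ("ground_truth", "ground_truth.json"),
        ]}
        self.reference.write(paths["reference_fasta"], paths["taxonomy"], paths["copy_numbers"])
        with open(paths["asv_fasta"], "w") as fh:
            for asv_id, seq in self.asv_sequences.items():
                fh.write(f">{asv_id}\n{seq}\n")
        self.asv_counts.rename_axis("asv_id").to_csv(paths["asv_counts"], sep="\t")
        self.microbiome_meta.rename_axis("sample").to_csv(paths["microbiome_metadata"])
        self.feature_table.to_csv(paths["features"], paths["feature_metadata"])
        write_mgf(self.spectra, paths["spectra"])
        self.truth.to_json(paths["ground_truth"])
        return paths


def simulate_study(design: SimulationDesign | None = None,
                   moiety_formula: str = "C3H6NO3S") -> SyntheticStudy:
    """Generate one complete synthetic study (all inputs + ground truth)."""
    design = design or SimulationDesign()
    ref = generate_reference_db(design.n_ref_taxa, design.seed)
    asv_seqs, counts, truth_m = generate_asv_data(ref, design)
    table, spectra, truth_f = generate_metabolomics_data(design, moiety_formula)
    micro_meta = pd.DataFrame({
        "sample": design.samples,
        "condition": [s.rsplit("__", 1)[0] for s in design.samples],
        "replicate": [int(s.rsplit("__r", 1)[1]) for s in design.samples],
    }).set_index("sample")
    return SyntheticStudy(
        design=design,
        reference=ref,
        asv_sequences=asv_seqs,
        asv_counts=counts,
        microbiome_meta=micro_meta,
        feature_table=table,
        spectra=spectra,
        truth=truth_m.merge(truth_f),
    )
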