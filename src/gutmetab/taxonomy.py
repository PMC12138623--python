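"""Multitaxonomy assignment (MTA) of 16S amplicon sequence variants.

An ASV is compared to every reference 16S sequence by semi-global alignment
identity. With M the best identity, every reference whose identity reaches
the adaptive threshold M - (1 - M)/4 is retained, and the retained lineages
are merged per rank into a "/"-joined multitaxonomy label. Abundances are
then renormalized by mean 16S rRNA gene copy numbers (rrnDB-style) so that
read counts better reflect cell counts.

The identity itself is matches / aligned-columns of the optimal global
alignment with free terminal gaps (match +1, mismatch -1, gap -2), the
standard semi-global scheme for amplicon-versus-reference comparison;
terminal-gap columns are excluded from the column count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "RANKS",
    "ReferenceDB",
    "TaxonomicAssignment",
    "AbundanceTable",
    "percent_identity",
    "mta_threshold",
    "assign_multitaxonomy",
    "assign_all",
    "aggregate_at_rank",
    "copy_number_normalize",
]

logger = logging.getLogger(__name__)

#: The six taxonomic ranks carried by every reference lineage, coarse to fine.
RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class RefRecord:
    id: str
    sequence: str
    lineage: dict[str, str]  # rank -> taxon name, complete over RANKS


@dataclass
class ReferenceDB:
    """16S reference sequences with 6-rank lineages and mean copy numbers.

    ``copy_numbers`` maps ``(rank, taxon_name)`` to the mean 16S rRNA gene
    copy number of genomes under that taxon.
    """

    records: list[RefRecord]
    copy_numbers: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        for r in self.records:
            for rank in RANKS:
                if not r.lineage.get(rank):
                    raise ValueError(f"reference {r.id} has an empty {rank}")
        for key, v in self.copy_numbers.items():
            if not v > 0:
                raise ValueError(f"copy number for {key} must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_files(cls, fasta_path, taxonomy_path, copy_numbers_path=None) -> "ReferenceDB":
        """Load from FASTA + taxonomy TSV (id, semicolon lineage) + copies TSV."""
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
        records = []
        for _, row in tax.iterrows():
            names = row["lineage"].split(";")
            if len(names) != len(RANKS):
                raise ValueError(f"lineage for {row['id']} must have {len(RANKS)} ranks")
            records.append(RefRecord(row["id"], seqs[row["id"]], dict(zip(RANKS, names))))
        copies: dict[tuple[str, str], float] = {}
        if copy_numbers_path is not None:
            cn = pd.read_csv(copy_numbers_path, sep="\t")
            copies = {(r["rank"], r["taxon"]): float(r["copies"]) for _, r in cn.iterrows()}
        return cls(records, copies)

    def write(self, fasta_path, taxonomy_path, copy_numbers_path) -> None:
        with open(fasta_path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}\n{r.sequence}\n")
        pd.DataFrame(
            {"id": [r.id for r in self.records],
             "lineage": [";".join(r.lineage[k] for k in RANKS) for r in self.records]}
        ).to_csv(taxonomy_path, sep="\t", index=False)
        rows = [{"rank": k[0], "taxon": k[1], "copies": v} for k, v in sorted(self.copy_numbers.items())]
        pd.DataFrame(rows, columns=["rank", "taxon", "copies"]).to_csv(copy_numbers_path, sep="\t", index=False)


@dataclass
class TaxonomicAssignment:
    """Result of MTA for one ASV: best identity, threshold, merged labels."""

    asv_id: str
    max_identity: float
    threshold: float
    retained_refs: list[str]
    label_per_rank: dict[str, str]

    def __post_init__(self) -> None:
        if not self.retained_refs:
            raise ValueError("an assignment must retain at least one reference")


@dataclass
class AbundanceTable:
    """Taxa x samples abundances at one rank; may be copy-number normalized."""

    rank: str
    matrix: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.normalized:
            sums = self.matrix.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized table columns must sum to 1")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free terminal gaps (semi-global)
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    else:  # older Biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()
_ALPHABET = set("ACGTN")


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Alignment identity between two nucleotide sequences, in [0, 1].

    Matches divided by aligned columns of the optimal semi-global alignment;
    columns inside terminal gaps are excluded, internal gap columns count as
    non-matching columns.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    for s in (seq_a, seq_b):
        extra = set(s) - _ALPHABET
        if extra:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(extra)}")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    g_a, g_b = str(aln[0]), str(aln[1])
    cols = [(x, y) for x, y in zip(g_a, g_b)]
    # trim terminal-gap columns from both ends
    lo = 0
    while lo < len(cols) and ("-" in cols[lo]):
        lo += 1
    hi = len(cols)
    while hi > lo and ("-" in cols[hi - 1]):
        hi -= 1
    trimmed = cols[lo:hi]
    if not trimmed:
        return 0.0
    matches = sum(1 for x, y in trimmed if x == y)
    return matches / len(trimmed)


def mta_threshold(max_identity: float) -> float:
    """Adaptive retention threshold M - (1 - M)/4 for best identity M."""
    if not 0.0 <= max_identity <= 1.0:
        raise ValueError(f"identity must lie in [0, 1], got {max_identity}")
    return max_identity - (1.0 - max_identity) / 4.0


def _merge_labels(refs: list[RefRecord]) -> dict[str, str]:
    return {
        rank: "/".join(sorted({r.lineage[rank] for r in refs}))
        for rank in RANKS
    }


def assign_multitaxonomy(asv_id: str, sequence: str, ref: ReferenceDB) -> TaxonomicAssignment:
    """Assign one ASV by the multitaxonomy rule.

    All references whose identity reaches ``mta_threshold(M)`` (inclusive, so
    the best hit is always retained) contribute their lineage; per rank the
    distinct names are alphabetically sorted and joined with "/".
    """
    if len(ref) == 0:
        raise ValueError("reference database is empty")
    identities = np.array([percent_identity(sequence, r.sequence) for r in ref.records])
    m = float(identities.max())
    thr = mta_threshold(m)
    retained = [r for r, ident in zip(ref.records, identities) if ident >= thr]
    return TaxonomicAssignment(
        asv_id=asv_id,
        max_identity=m,
        threshold=thr,
        retained_refs=[r.id for r in retained],
        label_per_rank=_merge_labels(retained),
    )


def assign_all(asv_sequences: dict[str, str], ref: ReferenceDB) -> list[TaxonomicAssignment]:
    """Assign every ASV in ``asv_sequences`` (id -> sequence)."""
    return [assign_multitaxonomy(asv_id, seq, ref) for asv_id, seq in asv_sequences.items()]


def assignments_to_frame(assignments: list[TaxonomicAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {"asv_id": a.asv_id, "max_identity": a.max_identity, "threshold": a.threshold,
               "retained_refs": ",".join(a.retained_refs)}
        row.update({rank: a.label_per_rank[rank] for rank in RANKS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("asv_id")


def aggregate_at_rank(
    assignments: list[TaxonomicAssignment], counts: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum ASV rows sharing an identical multitaxonomy label at ``rank``.

    Per-sample totals are conserved. Raises if a counted ASV lacks an
    assignment.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    labels = {a.asv_id: a.label_per_rank[rank] for a in assignments}
    missing = [asv for asv in counts.index if asv not in labels]
    if missing:
        raise ValueError(f"ASVs without assignment: {missing}")
    out = counts.groupby([labels[a] for a in counts.index]).sum()
    out.index.name = rank
    return out


def _label_copy_number(
    label: str, rank: str, copy_numbers: dict[tuple[str, str], float]
) -> float:
    """Mean copy number over a multitaxonomy label's member taxa.

    Falls back to the database-wide mean at the same rank, then to the global
    mean, with a logged warning; raises only when no copy number exists at all.
    """
    members = [copy_numbers[(rank, name)] for name in label.split("/") if (rank, name) in copy_numbers]
    if members:
        return float(np.mean(members))
    rank_values = [v for (rk, _), v in copy_numbers.items() if rk == rank]
    if rank_values:
        logger.warning("no copy number for %r at %s; using rank mean", label, rank)
        return float(np.mean(rank_values))
    if copy_numbers:
        logger.warning("no copy number for %r at %s; using database mean", label, rank)
        return float(np.mean(list(copy_numbers.values())))
    raise KeyError(f"no copy number available for taxon {label!r} at rank {rank}")


def copy_number_normalize(
    counts: pd.DataFrame, copy_numbers: dict[tuple[str, str], float], rank: str
) -> AbundanceTable:
    """Divide each taxon's counts by its mean 16S copy number and re-close.

    Multitaxonomy labels use the mean copy number over their member taxa.
    Each sample column is re-closed to relative abundance (sums to 1).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    copies = pd.Series({label: _label_copy_number(label, rank, copy_numbers) for label in counts.index})
    corrected = counts.div(copies, axis=0)
    col_sums = corrected.sum(axis=0)
    if (col_sums <= 0).any():
        bad = list(col_sums.index[col_sums <= 0])
        raise ValueError(f"samples with zero total abundance: {bad}")
    return AbundanceTable(rank=rank, matrix=corrected.div(col_sums, axis=1), normalized=True)
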