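"""Feature-based molecular networking and biotransformation annotation.

Spectral similarity uses the modified cosine: fragment peaks match either at
equal m/z (within a tolerance) or offset by the precursor mass difference, so
that structurally related molecules — e.g. a parent compound and a conjugated
microbial metabolite — still score highly. Pairs passing the cosine and
matched-peak thresholds form an undirected molecular network, and networked
pairs whose precursor mass delta matches a chemical moiety (allowing a +-H
ambiguity inherent to conjugation chemistry) are reported as
biotransformation candidates, flagged when the abundance fold changes move
in opposite directions upon microbial exposure.

Default thresholds: fragment tolerance 0.005 Da, cosine >= 0.7, >= 4 matched
peaks, 10 ppm for moiety deltas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .masses import PROTON_MASS, monoisotopic_mass  # noqa: F401  (proton re-exported for adduct math)

__all__ = [
    "SpectrumRecord",
    "NetworkParams",
    "NetworkEdge",
    "BiotransformationCandidate",
    "modified_cosine",
    "build_network",
    "annotate_mass_shift",
    "find_biotransformation_candidates",
    "mirror_data",
    "read_mgf",
    "write_mgf",
]


@dataclass(frozen=True)
class SpectrumRecord:
    """One MS/MS spectrum: precursor m/z plus a peak list sorted by m/z."""

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        if (self.intensity <= 0).any():
            raise ValueError("peak intensities must be positive")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")

    @property
    def n_peaks(self) -> int:
        return self.mz.size

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class NetworkParams:
    fragment_tol: float = 0.005  # Da
    cosine_min: float = 0.7
    min_matches: int = 4
    sqrt_transform: bool = True

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.cosine_min <= 0 or self.min_matches <= 0:
            raise ValueError("all networking thresholds must be positive")


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    cosine: float
    n_matched: int
    delta_mz: float  # target precursor - source precursor


@dataclass(frozen=True)
class BiotransformationCandidate:
    parent_id: str
    product_id: str
    delta_mass: float
    moiety: str
    variant: str  # "M", "M-H" or "M+H"
    ppm_error: float
    direction_consistent: bool | None = None


def _weights(spec: SpectrumRecord, sqrt_transform: bool) -> np.ndarray:
    w = np.sqrt(spec.intensity) if sqrt_transform else spec.intensity.astype(float)
    return w / np.linalg.norm(w)


def candidate_pairs(a: SpectrumRecord, b: SpectrumRecord, params: NetworkParams):
    """All (i, j, weight-product) fragment pairs matching directly or shifted
    by the precursor mass difference."""
    wa, wb = _weights(a, params.sqrt_transform), _weights(b, params.sqrt_transform)
    shift = b.precursor_mz - a.precursor_mz
    pairs = {}
    for offset in (0.0, shift):
        di = np.abs(a.mz[:, None] + offset - b.mz[None, :])
        for i, j in zip(*np.nonzero(di <= params.fragment_tol)):
            pairs[(int(i), int(j))] = float(wa[i] * wb[j])
    return pairs


def modified_cosine(a: SpectrumRecord, b: SpectrumRecord, params: NetworkParams = NetworkParams()):
    """Modified cosine similarity and matched-peak count between two spectra.

    Peaks are matched greedily by descending intensity product, each peak used
    at most once; intensities are square-root transformed and unit-normalized
    before scoring. Returns ``(cosine, n_matched)`` with cosine in [0, 1].
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("spectra must be nonempty")
    pairs = candidate_pairs(a, b, params)
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    n_matched = 0
    for (i, j), w in sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0])):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += w
        n_matched += 1
    return min(score, 1.0), n_matched


def dedupe_spectra(spectra: list[SpectrumRecord]) -> list[SpectrumRecord]:
    """Keep the highest-TIC spectrum per feature id."""
    best: dict[str, SpectrumRecord] = {}
    for s in spectra:
        if s.feature_id not in best or s.tic > best[s.feature_id].tic:
            best[s.feature_id] = s
    return list(best.values())


def build_network(spectra: list[SpectrumRecord], params: NetworkParams = NetworkParams()) -> list[NetworkEdge]:
    """Molecular network: edges for pairs with cosine >= cosine_min and
    n_matched >= min_matches."""
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    spectra = dedupe_spectra(spectra)
    edges = []
    for i, a in enumerate(spectra):
        for b in spectra[i + 1:]:
            cos, n = modified_cosine(a, b, params)
            if cos >= params.cosine_min and n >= params.min_matches:
                edges.append(NetworkEdge(a.feature_id, b.feature_id, cos, n,
                                         b.precursor_mz - a.precursor_mz))
    return edges


def edges_to_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"source": e.source, "target": e.target, "cosine": e.cosine,
          "n_matched": e.n_matched, "delta_mz": e.delta_mz} for e in edges],
        columns=["source", "target", "cosine", "n_matched", "delta_mz"],
    )


def to_networkx(spectra: list[SpectrumRecord], edges: list[NetworkEdge]):
    import networkx as nx

    g = nx.Graph()
    for s in dedupe_spectra(spectra):
        g.add_node(s.feature_id, precursor_mz=s.precursor_mz)
    for e in edges:
        g.add_edge(e.source, e.target, cosine=e.cosine, n_matched=e.n_matched, delta_mz=e.delta_mz)
    return g


# hydrogen-count ambiguity of conjugation chemistry: the observed precursor
# delta may be the moiety mass, or that mass +- one hydrogen
_H = monoisotopic_mass("H")
_VARIANTS = (("M", 0.0), ("M-H", -_H), ("M+H", +_H))


def annotate_mass_shift(
    parent: SpectrumRecord,
    product: SpectrumRecord,
    moieties: list[str],
    ppm_tol: float = 10.0,
    fold_changes=None,
) -> list[BiotransformationCandidate]:
    """Compare the precursor delta (product - parent) against moiety masses.

    Each moiety is tried at its monoisotopic mass and at +-1 H. Matches
    within ``ppm_tol`` (ppm of the moiety mass) become candidates; when a
    fold-change result is supplied, ``direction_consistent`` flags pairs
    whose parent decreased and product increased upon inoculation.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if not moieties:
        raise ValueError("at least one moiety formula is required")
    delta = product.precursor_mz - parent.precursor_mz
    out = []
    for moiety in moieties:
        m0 = monoisotopic_mass(moiety)
        if m0 <= 0:
            continue
        for variant, dh in _VARIANTS:
            expected = m0 + dh
            ppm = (delta - expected) / expected * 1e6
            if abs(ppm) <= ppm_tol:
                consistent = None
                if fold_changes is not None:
                    consistent = bool(
                        fold_changes.log2fc(parent.feature_id) < 0 < fold_changes.log2fc(product.feature_id)
                    )
                out.append(BiotransformationCandidate(
                    parent.feature_id, product.feature_id, delta, moiety, variant,
                    float(ppm), consistent,
                ))
    return out


def find_biotransformation_candidates(
    spectra: list[SpectrumRecord],
    moieties: list[str],
    ppm_tol: float = 10.0,
    fold_changes=None,
    params: NetworkParams = NetworkParams(),
    edges: list[NetworkEdge] | None = None,
) -> list[BiotransformationCandidate]:
    """Scan the molecular network for moiety-mass precursor deltas.

    Every edge is tried in both parent->product orientations (only the
    positive-delta orientation can match a positive moiety mass).
    """
    by_id = {s.feature_id: s for s in dedupe_spectra(spectra)}
    if edges is None:
        edges = build_network(spectra, params)
    out = []
    for e in edges:
        a, b = by_id[e.source], by_id[e.target]
        for parent, product in ((a, b), (b, a)):
            out.extend(annotate_mass_shift(parent, product, moieties, ppm_tol, fold_changes))
    return out


def mirror_data(a: SpectrumRecord, b: SpectrumRecord, params: NetworkParams = NetworkParams()) -> pd.DataFrame:
    """Paired peak list for a mirror plot: spectrum ``b`` negated.

    Intensities are normalized to the base peak of each spectrum; matched
    status follows the same greedy matching as ``modified_cosine``.
    """
    pairs = candidate_pairs(a, b, params)
    used_a: set[int] = set()
    used_b: set[int] = set()
    for (i, j), _ in sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0])):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
    rows = []
    for spec, used, sign, label in ((a, used_a, 1.0, "top"), (b, used_b, -1.0, "bottom")):
        base = spec.intensity.max()
        for k in range(spec.n_peaks):
            rows.append({"spectrum": label, "feature_id": spec.feature_id,
                         "mz": float(spec.mz[k]),
                         "intensity": sign * float(spec.intensity[k] / base),
                         "matched": k in used})
    return pd.DataFrame(rows)


def read_mgf(path) -> list[SpectrumRecord]:
    """Read MS/MS spectra from an MGF file (TITLE = feature id)."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            out.append(SpectrumRecord(
                feature_id=str(entry["params"]["title"]),
                precursor_mz=float(entry["params"]["pepmass"][0]),
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
            ))
    return out


def write_mgf(spectra: list[SpectrumRecord], path) -> None:
    entries = [
        {"m/z array": s.mz, "intensity array": s.intensity,
         "params": {"title": s.feature_id, "pepmass": s.precursor_mz}}
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")
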