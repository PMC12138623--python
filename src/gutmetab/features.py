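"""LC-MS feature-table handling: blank filtering, fold changes, PCA.

A feature table is an MZmine-style export: one row per aligned feature
(id, precursor m/z, retention time) and one raw peak-area column per sample.
Samples carry roles (crude extract, fecal-inoculated extract, blank, qc)
from a metadata file; crude and inoculated samples sharing a condition and
replicate index are treated as paired for the signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .stats import rank_sum_test, signed_rank_test

__all__ = ["FeatureTable", "FoldChangeResult", "blank_filter", "fold_change", "pca_scores"]

ROLES = ("crude", "inoculated", "blank", "qc")


@dataclass
class FeatureTable:
    """Feature x sample peak areas with per-feature m/z and retention time.

    ``features`` is indexed by feature id with columns ``mz`` (Da) and ``rt``
    (minutes); ``intensities`` shares that index and has one column per
    sample; ``sample_meta`` is indexed by sample with columns ``role`` and,
    optionally, ``condition`` and ``replicate`` used for pairing.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if not (self.features["mz"] > 0).all():
            raise ValueError("feature m/z must be positive")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("peak areas must be nonnegative")
        missing = [s for s in self.intensities.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without a role: {missing}")
        bad = set(self.sample_meta["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    def samples_with_role(self, role: str) -> list[str]:
        keep = self.sample_meta.index[self.sample_meta["role"] == role]
        return [s for s in self.intensities.columns if s in set(keep)]

    @classmethod
    def from_csv(cls, features_csv, metadata_csv) -> "FeatureTable":
        """Read an MZmine-style CSV (id, mz, rt, per-sample columns) + metadata."""
        df = pd.read_csv(features_csv)
        df = df.rename(columns={"row ID": "id", "row m/z": "mz", "row retention time": "rt"})
        df = df.set_index(df["id"].astype(str)).drop(columns=["id"])
        df.columns = [c.removesuffix(" Peak area").strip() for c in df.columns]
        meta = pd.read_csv(metadata_csv, dtype={"sample": str}).set_index("sample")
        sample_cols = [c for c in df.columns if c in set(meta.index)]
        return cls(features=df[["mz", "rt"]].astype(float),
                   intensities=df[sample_cols].astype(float),
                   sample_meta=meta)

    def to_csv(self, features_csv, metadata_csv=None) -> None:
        out = pd.concat([self.features, self.intensities], axis=1)
        out.rename_axis("id").to_csv(features_csv)
        if metadata_csv is not None:
            self.sample_meta.rename_axis("sample").to_csv(metadata_csv)


@dataclass
class FoldChangeResult:
    """Per-feature log2 fold change (inoculated / crude) with Wilcoxon p."""

    table: pd.DataFrame  # columns: log2fc, statistic, p_value, test
    paired: bool = True
    pseudo_intensity: float = 0.0

    def log2fc(self, feature_id: str) -> float:
        return float(self.table.loc[feature_id, "log2fc"])


def blank_filter(table: FeatureTable, min_ratio: float = 3.0) -> FeatureTable:
    """Drop features whose mean sample intensity is below ``min_ratio`` times
    the mean blank intensity. Idempotent; blank columns are retained so the
    filter can be re-applied."""
    blanks = table.samples_with_role("blank")
    if not blanks:
        raise ValueError("no blank samples present; blank filtering is not configured")
    non_blank = [s for s in table.intensities.columns if s not in set(blanks)]
    sample_mean = table.intensities[non_blank].mean(axis=1)
    blank_mean = table.intensities[blanks].mean(axis=1)
    keep = sample_mean >= min_ratio * blank_mean
    return FeatureTable(
        features=table.features.loc[keep].copy(),
        intensities=table.intensities.loc[keep].copy(),
        sample_meta=table.sample_meta.copy(),
    )


def _pairing(meta: pd.DataFrame, crude: list[str], inoc: list[str]) -> list[tuple[str, str]] | None:
    if not {"condition", "replicate"}.issubset(meta.columns):
        return None
    key = lambda s: (meta.loc[s, "condition"], meta.loc[s, "replicate"])
    by_key = {key(s): s for s in crude}
    pairs = [(by_key[key(s)], s) for s in inoc if key(s) in by_key]
    if len(pairs) != len(inoc) or len(pairs) != len(crude):
        return None
    return pairs


def fold_change(table: FeatureTable, pseudo_intensity: float | None = None) -> FoldChangeResult:
    """log2(mean inoculated / mean crude) per feature, with a Wilcoxon test.

    Zeros are offset by a pseudo-intensity (default: half the smallest
    nonzero value in the table) so fold changes stay finite. The signed-rank
    test is used when crude and inoculated samples pair up by condition and
    replicate; otherwise the rank-sum test is used and flagged.
    """
    crude = table.samples_with_role("crude")
    inoc = table.samples_with_role("inoculated")
    if len(crude) < 2 or len(inoc) < 2:
        raise ValueError("need >= 2 crude and >= 2 inoculated samples")
    x = table.intensities
    if pseudo_intensity is None:
        nz = x.to_numpy()[x.to_numpy() > 0]
        pseudo_intensity = float(nz.min()) / 2.0 if nz.size else 1.0
    xs = x + pseudo_intensity
    pairs = _pairing(table.sample_meta, crude, inoc)
    rows = []
    for fid in x.index:
        l2fc = float(np.log2(xs.loc[fid, inoc].mean() / xs.loc[fid, crude].mean()))
        if pairs is not None:
            res = signed_rank_test([xs.loc[fid, i] - xs.loc[fid, c] for c, i in pairs])
            test = "signed-rank"
        else:
            res = rank_sum_test(xs.loc[fid, inoc].to_numpy(), xs.loc[fid, crude].to_numpy())
            test = "rank-sum"
        rows.append({"id": fid, "log2fc": l2fc, "statistic": res.statistic,
                     "p_value": res.p_value, "test": test})
    return FoldChangeResult(
        table=pd.DataFrame(rows).set_index("id"),
        paired=pairs is not None,
        pseudo_intensity=pseudo_intensity,
    )


def pca_scores(table: FeatureTable, n_components: int = 2, roles=("crude", "inoculated")):
    """PCA of log10(peak area + 1) profiles, centered, unscaled.

    Returns (scores DataFrame samples x PCs, explained variance ratios).
    """
    samples = [s for r in roles for s in table.samples_with_role(r)]
    x = np.log10(table.intensities[samples].to_numpy(dtype=float).T + 1.0)
    max_comp = min(x.shape)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return (
        pd.DataFrame(scores, index=samples, columns=[f"PC{i+1}" for i in range(n_components)]),
        model.explained_variance_ratio_,
    )
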