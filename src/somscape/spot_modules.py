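"""Overexpression spot modules on the metagene grid.

A spot is an 8-connected region of grid pixels whose summary-map value
exceeds a per-map threshold percentile; its gene list is the set of genes
whose best-matching unit falls inside the region, and its per-sample
expression profile is the mean metagene expression over the region.
Surviving spots are labeled A, B, ... in descending order of peak map
value. Downstream utilities assess subtype classification power (ROC
AUC), combine spot tuples on the ternary simplex, build weighted
topological overlap (wTO) networks between spots, and split the cohort
on a liver-contamination-like spot.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from somscape.som_portrayal import SOMResults

logger = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def _spot_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — enough labels for any spot count."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        lab = ""
        j = i
        while True:
            lab = letters[j % 26] + lab
            j = j // 26 - 1
            if j < 0:
                break
        out.append(lab)
    return out


@dataclass
class SpotModule:
    """One labeled overexpression spot."""

    label: str
    pixels: np.ndarray  # linear indices (row * width + col)
    peak_value: float
    genes: list[str] = field(default_factory=list)
    profile: pd.Series | None = None  # per-sample mean metagene expression

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


class SpotCollection:
    """Ordered collection of spot modules from one summary map."""

    def __init__(self, spots: list[SpotModule], grid_shape: tuple[int, int]):
        labels = [s.label for s in spots]
        if len(set(labels)) != len(labels):
            raise ValueError("spot labels must be unique")
        self.spots = spots
        self.grid_shape = grid_shape  # (height, width)

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def __getitem__(self, label: str) -> SpotModule:
        for s in self.spots:
            if s.label == label:
                return s
        raise KeyError(f"no spot {label!r}")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spots]

    def profiles(self) -> pd.DataFrame:
        """spots x samples matrix of spot expression profiles."""
        rows = {s.label: s.profile for s in self.spots if s.profile is not None}
        return pd.DataFrame(rows).T

    def to_gmt(self, path) -> None:
        from somscape.geneset_analysis import GeneSetCollection

        sets = {s.label: s.genes for s in self.spots if s.genes}
        descs = {s.label: f"spot {s.label} ({s.n_pixels} pixels)" for s in self.spots}
        GeneSetCollection(sets, descriptions=descs).to_gmt(path)

    def membership_table(self) -> pd.DataFrame:
        """One row per (spot, pixel): label, linear index, row, col."""
        height, width = self.grid_shape
        rows = []
        for s in self.spots:
            for p in s.pixels:
                rows.append({"spot": s.label, "pixel": int(p), "row": int(p) // width, "col": int(p) % width})
        return pd.DataFrame(rows, columns=["spot", "pixel", "row", "col"])


def _split_component(map2d: np.ndarray, comp: np.ndarray, threshold: float, split_depth: float):
    """Split one above-threshold component at its significant local maxima.

    Components holding two or more local maxima separated by a valley
    deeper than ``split_depth`` x (component peak - threshold) are divided
    by a watershed seeded at those maxima; a component with a single
    significant peak (including flat plateaus) is returned whole.
    """
    from skimage.morphology import h_maxima
    from skimage.segmentation import watershed

    h = split_depth * (map2d[comp].max() - threshold)
    if h <= 0:
        return [comp]
    seeds = h_maxima(np.where(comp, map2d - threshold, 0.0), h) & comp
    markers, n_seeds = ndimage.label(seeds, structure=_EIGHT_CONNECTED)
    if n_seeds < 2:
        return [comp]
    ws = watershed(-map2d, markers=markers, mask=comp, connectivity=2)
    return [ws == j for j in range(1, n_seeds + 1)]


def _connected_overexpression(
    map2d: np.ndarray,
    threshold_percentile: float,
    min_pixels: int,
    split_merged: bool = True,
    split_depth: float = 0.1,
):
    """Label 8-connected components above the per-map percentile threshold."""
    threshold = np.percentile(map2d, threshold_percentile)
    mask = map2d > threshold
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    comps = []
    for i in range(1, n + 1):
        comp = labeled == i
        parts = (
            _split_component(map2d, comp, threshold, split_depth) if split_merged else [comp]
        )
        for part in parts:
            idx = np.flatnonzero(part.ravel())
            if len(idx) >= min_pixels:
                comps.append((idx, float(map2d.ravel()[idx].max())))
    return comps


def detect_spots(
    summary_map: np.ndarray,
    model: "SOMResults | None" = None,
    threshold_percentile: float = 86.0,
    min_pixels: int = 4,
    split_merged: bool = True,
    split_depth: float = 0.1,
) -> SpotCollection:
    """Extract overexpression spots from a summary map.

    Pixels above the map's ``threshold_percentile`` are grouped into
    8-connected components; components smaller than ``min_pixels`` are
    dropped; survivors are labeled A, B, ... by descending peak map value.
    Because co-expression modules tile the border of a trained map, two
    modules can abut with no sub-threshold gap between them; with
    ``split_merged`` (the default) a component holding several local maxima
    separated by a valley deeper than ``split_depth`` of its height above
    threshold is divided between the maxima by a watershed. If a fitted
    ``model`` is given, each spot gets its gene list and per-sample
    expression profile. An empty collection is returned (and logged) when
    nothing survives.
    """
    summary_map = np.asarray(summary_map, dtype=float)
    comps = _connected_overexpression(
        summary_map, threshold_percentile, min_pixels, split_merged, split_depth
    )
    comps.sort(key=lambda c: (-c[1], c[0][0]))
    labels = _spot_labels(len(comps))
    spots = []
    for lab, (pixels, peak) in zip(labels, comps):
        spot = SpotModule(label=lab, pixels=pixels, peak_value=peak)
        if model is not None:
            spot.genes = model.genes_of_pixels(pixels)
            spot.profile = spot_expression(model, pixels, label=lab)
        spots.append(spot)
    if not spots:
        logger.info(
            "no spots survived (threshold percentile %.1f, min pixels %d)",
            threshold_percentile,
            min_pixels,
        )
    return SpotCollection(spots, grid_shape=summary_map.shape)


def spot_expression(model: "SOMResults", pixels, label: str | None = None) -> pd.Series:
    """Per-sample mean metagene expression over a pixel set (linear indices)."""
    pixels = np.atleast_1d(np.asarray(pixels, dtype=int)).ravel()
    if pixels.min() < 0 or pixels.max() >= model.n_metagenes:
        raise IndexError("spot pixels outside the model grid")
    prof = model.prototypes.to_numpy()[pixels].mean(axis=0)
    return pd.Series(prof, index=model.samples, name=label)


def sort_samples_by_spot(
    profiles: pd.DataFrame, spot: str, subtypes: pd.Series | None = None
) -> list[str]:
    """Sample order of increasing expression of ``spot``.

    With ``subtypes`` given, samples are grouped by subtype (in label sort
    order) and ordered within each group.
    """
    values = profiles.loc[spot]
    if subtypes is None:
        return list(values.sort_values(kind="stable").index)
    subtypes = subtypes.reindex(values.index)
    order = []
    for g in sorted(subtypes.unique(), key=str):
        members = values[subtypes == g].sort_values(kind="stable")
        order.extend(members.index)
    return order


def count_sample_spots(
    portrait: np.ndarray,
    threshold_percentile: float = 98.0,
    min_pixels: int = 4,
    split_merged: bool = True,
    split_depth: float = 0.1,
) -> int:
    """Number of overexpression spots in one individual portrait.

    Uses the same detection rule as :func:`detect_spots`; a flat portrait
    has zero spots, and adding a constant to the portrait never changes
    the count (the threshold is a percentile, the split depth relative).
    """
    portrait = np.asarray(portrait, dtype=float)
    if np.ptp(portrait) == 0:
        return 0
    return len(
        _connected_overexpression(portrait, threshold_percentile, min_pixels, split_merged, split_depth)
    )


def spot_auc(profile: pd.Series, labels: pd.Series, target) -> float:
    """One-vs-rest ROC AUC of a spot profile for ``target`` subtype.

    Computed as the Mann-Whitney U statistic divided by n+ * n-, with ties
    getting half credit. Values below 0.5 are reported as-is: they mean
    under-expression of the spot marks the subtype.
    """
    profile = pd.Series(profile)
    labels = pd.Series(labels).reindex(profile.index)
    pos = profile[labels == target].to_numpy()
    neg = profile[labels != target].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"one-vs-rest AUC for {target!r} needs both classes nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def ternary_coordinates(values) -> np.ndarray:
    """Map triples of spot expression onto the 2-simplex.

    Negative components are clipped to 0, then each triple is normalized to
    sum 1; an all-zero triple maps to the centroid (1/3, 1/3, 1/3).
    Accepts one triple or an (n, 3) array.
    """
    arr = np.asarray(values, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError("ternary coordinates need exactly three values per sample")
    clipped = np.clip(arr, 0.0, None)
    totals = clipped.sum(axis=1, keepdims=True)
    out = np.where(totals > 0, clipped / np.where(totals == 0, 1.0, totals), 1.0 / 3.0)
    return out[0] if single else out


def wto_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Signed weighted topological overlap between spot profiles.

    With signed adjacency a_ij = Pearson correlation of spot profiles and
    connectivity k_i = sum_{k != i} |a_ik|:

        w_ij = (sum_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - |a_ij|)

    The diagonal is set to 1. The signed form keeps anticorrelation between
    spots visible as negative overlap.
    """
    if len(profiles) < 2:
        raise ValueError("wTO needs at least 2 spot profiles")
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = profiles.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"spot {bad!r} has a constant profile; correlation undefined")
    a = np.corrcoef(arr)
    np.fill_diagonal(a, 0.0)
    k = np.abs(a).sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - np.abs(a)
    w = numer / denom
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=profiles.index, columns=profiles.index)


def contamination_split(profile: pd.Series) -> tuple[pd.Series, float]:
    """Two-group split of a contamination-like spot profile.

    Complete-linkage hierarchical clustering of the 1-D profile cut at two
    clusters; the cluster with the larger mean is "high". Returns the
    per-sample labels and the high fraction. A constant profile degenerates
    to all-low with a warning.
    """
    profile = pd.Series(profile, dtype=float)
    if len(profile) < 2:
        raise ValueError("contamination split needs at least 2 samples")
    values = profile.to_numpy()
    if np.ptp(values) == 0:
        warnings.warn("constant spot profile; reporting all samples as 'low'")
        return pd.Series("low", index=profile.index), 0.0
    z = linkage(values.reshape(-1, 1), method="complete")
    groups = fcluster(z, t=2, criterion="maxclust")
    means = {g: values[groups == g].mean() for g in np.unique(groups)}
    high_group = max(means, key=lambda g: means[g])
    labels = pd.Series(np.where(groups == high_group, "high", "low"), index=profile.index)
    return labels, float((labels == "high").mean())
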