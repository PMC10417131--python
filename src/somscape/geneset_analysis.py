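"""Gene-set signature scoring (GSZ), grid density maps, and spot enrichment.

GSZ is a per-sample standardized mean: for sample *s* and gene set *G*
present in the matrix,

    GSZ(s) = (mean_{g in G} x_gs - mean_all x_.s) / (sd_all x_.s / sqrt(|G|))

so a set of average genes scores 0 and a singleton set reduces to the
gene's within-sample z-score. Centralized input is assumed, matching the
rest of the pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from somscape.preprocessing import ExpressionMatrix
    from somscape.som_portrayal import SOMResults


class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        self.sets: dict[str, set[str]] = {}
        self.descriptions = descriptions or {}
        for name, members in sets.items():
            if name in self.sets:
                raise ValueError(f"duplicate set name {name!r}")
            members = list(members)
            if not members:
                raise ValueError(f"empty gene set {name!r}")
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(f"set {name!r}: {len(members) - len(uniq)} duplicate members dropped")
            self.sets[name] = set(uniq)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def parse_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) <= 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line ({len(fields)} fields, need "
                    "name, description and at least one gene)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} has {len(members) - len(uniq)} "
                    "duplicate members; deduplicated"
                )
            sets[name] = uniq
            descriptions[name] = desc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # already warned with line numbers
        return GeneSetCollection(sets, descriptions)


def gsz_profile(matrix: "ExpressionMatrix", gene_set, name: str | None = None) -> pd.Series:
    """Per-sample gene set Z score of ``gene_set`` (iterable of gene IDs).

    Genes absent from the matrix are dropped (count logged via a warning if
    any); an entirely absent set is an error. Uses the sample standard
    deviation (ddof=1) over all genes within each sample.
    """
    genes = set(gene_set)
    present = [g for g in matrix.genes if g in genes]
    if not present:
        raise ValueError(f"no genes of set {name or '<unnamed>'!r} found in the matrix")
    n_missing = len(genes) - len(present)
    if n_missing:
        warnings.warn(
            f"gsz_profile: {n_missing}/{len(genes)} genes of set {name or '<unnamed>'!r} "
            "absent from the matrix; dropped"
        )
    arr = matrix.values.to_numpy()
    sub = matrix.values.loc[present].to_numpy()
    mean_all = arr.mean(axis=0)
    sd_all = arr.std(axis=0, ddof=1)
    score = (sub.mean(axis=0) - mean_all) / (sd_all / np.sqrt(len(present)))
    return pd.Series(score, index=matrix.samples, name=name or "GSZ")


def gsz_matrix(matrix: "ExpressionMatrix", collection: GeneSetCollection) -> pd.DataFrame:
    """GSZ scores for every set in a collection: sets x samples."""
    rows = {}
    for name in collection:
        try:
            rows[name] = gsz_profile(matrix, collection[name], name=name)
        except ValueError:
            warnings.warn(f"set {name!r} has no genes in the matrix; skipped")
    return pd.DataFrame(rows).T


def set_density_map(model: "SOMResults", gene_set, smooth_sigma: float = 0.0) -> np.ndarray:
    """Grid image counting the set's genes assigned to each metagene pixel.

    Pixel values sum to the number of set genes present in the model.
    ``smooth_sigma`` > 0 applies a Gaussian blur for display (the unsmoothed
    counts are what the conservation property refers to).
    """
    genes = set(gene_set)
    counts = np.zeros(model.height * model.width)
    idx = [model.gene_index[g] for g in genes if g in model.gene_index]
    np.add.at(counts, model.assignments[idx], 1)
    image = counts.reshape(model.height, model.width)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, smooth_sigma)
    return image


def spot_overrepresentation(
    spot_genes,
    collection: GeneSetCollection,
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of every set in a spot's gene list.

    One-sided tail P(X >= overlap) with BH correction across the collection;
    fold enrichment = observed / expected overlap.
    """
    spot = set(spot_genes)
    if not spot:
        raise ValueError("empty spot gene list")
    if universe_size < len(spot):
        raise ValueError("universe smaller than the spot gene list")
    rows = []
    for name in collection:
        members = collection[name]
        overlap = len(spot & members)
        expected = len(spot) * len(members) / universe_size
        p = stats.hypergeom.sf(overlap - 1, universe_size, len(members), len(spot))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": overlap,
                "expected": expected,
                "fold": overlap / expected if expected > 0 else np.nan,
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value")
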