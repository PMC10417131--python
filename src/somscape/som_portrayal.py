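"""SOM portrayal: map gene expression profiles onto a 2D metagene grid.

The model clusters the per-gene expression profiles (vectors across
samples) with a batch-trained self-organizing map on a planar rectangular
grid, by default 50 x 50 = 2500 metagenes. Each grid node carries a
prototype profile (its "metagene"); reading the prototype matrix
column-wise for one sample yields that sample's expression portrait.

Training is batch mode with a Gaussian neighborhood whose radius anneals
linearly from half the grid width to 1, prototypes initialized on the
plane spanned by the first two principal components of the gene cloud,
and Euclidean best-matching-unit distances. Equidistant prototypes
resolve to the lowest linear index. Grid convention: pixel (col, row),
origin top-left, linear index = row * width + col.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from somscape.preprocessing import ExpressionMatrix


@dataclass
class SupportingMaps:
    """Per-pixel summary images of a trained model (height x width arrays)."""

    variance: np.ndarray  # per-metagene variance across samples
    population: np.ndarray  # genes assigned per metagene
    group_summary: np.ndarray | None = None  # pixelwise max over group means
    personalized_summary: np.ndarray | None = None  # pixelwise quantile over portraits


class SOMPortrayal:
    """Self-organizing-map portrayal model for a centralized expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Centralized (row mean 0) log-expression, genes x samples.
    grid : tuple of int
        (width, height) of the metagene grid; default (50, 50).
    epochs : int
        Number of batch training sweeps.
    seed : int
        Randomness is only used for degenerate initialization fallbacks;
        kept for the reproducibility contract.

    Examples
    --------
    >>> results = SOMPortrayal(matrix, grid=(50, 50)).fit()
    >>> img = results.portrait("S001")
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        grid: tuple[int, int] = (50, 50),
        epochs: int = 30,
        seed: int = 0,
        sigma_start: float | None = None,
        sigma_end: float = 1.0,
    ):
        if matrix.shape[0] == 0 or matrix.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if matrix.scale != "centralized":
            raise ValueError(
                f"SOM training expects centralized input, got scale={matrix.scale!r}; "
                "run somscape.centralize first"
            )
        width, height = grid
        if width < 1 or height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if width * height > matrix.shape[0]:
            warnings.warn(
                f"grid has more metagenes ({width * height}) than genes ({matrix.shape[0]})"
            )
        self.matrix = matrix
        self.width, self.height = width, height
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.sigma_start = sigma_start if sigma_start is not None else max(width, height) / 2.0
        self.sigma_end = float(sigma_end)

    # ------------------------------------------------------------------
    def _grid_coords(self) -> np.ndarray:
        """(n_units, 2) array of (col, row) per linear index row*width+col."""
        rows, cols = np.divmod(np.arange(self.width * self.height), self.width)
        # linear index = row*width + col -> row = idx // width, col = idx % width
        return np.column_stack([cols, rows]).astype(float)

    def _init_prototypes(self, X: np.ndarray) -> np.ndarray:
        """Place prototypes on the plane of the first two principal components."""
        n_units = self.width * self.height
        mean = X.mean(axis=0)
        Xc = X - mean
        # top-2 right singular vectors of the gene cloud in sample space
        try:
            _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        except np.linalg.LinAlgError:  # pragma: no cover - pathological input
            rng = np.random.default_rng(self.seed)
            return rng.normal(0, 1e-3, size=(n_units, X.shape[1]))
        sd = s / np.sqrt(max(X.shape[0] - 1, 1))
        coords = self._grid_coords()
        a1 = np.linspace(-2.0, 2.0, self.width)[coords[:, 0].astype(int)]
        a2 = np.linspace(-2.0, 2.0, self.height)[coords[:, 1].astype(int)]
        proto = mean[None, :] + np.outer(a1 * sd[0], Vt[0])
        if X.shape[1] > 1 and len(sd) > 1:
            proto = proto + np.outer(a2 * sd[1], Vt[1])
        return proto

    def fit(self) -> "SOMResults":
        """Batch-train the map and return the fitted results object."""
        X = np.ascontiguousarray(self.matrix.values.to_numpy(), dtype=np.float32)
        n_units = self.width * self.height
        coords = self._grid_coords()
        grid_d2 = (
            (coords[:, None, 0] - coords[None, :, 0]) ** 2
            + (coords[:, None, 1] - coords[None, :, 1]) ** 2
        ).astype(np.float32)

        proto = self._init_prototypes(X.astype(np.float64)).astype(np.float32)
        sigmas = np.linspace(self.sigma_start, self.sigma_end, max(self.epochs, 1))
        qe_trace = []
        bmu = np.zeros(X.shape[0], dtype=np.int64)
        x_sq = (X**2).sum(axis=1)

        for epoch, sigma in enumerate(sigmas):
            p_sq = (proto**2).sum(axis=1)
            d2 = x_sq[:, None] - 2.0 * (X @ proto.T) + p_sq[None, :]
            bmu = np.argmin(d2, axis=1)
            if epoch > 0:
                # QE of the prototypes after the previous update; the
                # pre-training (initialization) error is not part of the trace
                qe = float(np.sqrt(np.maximum(d2[np.arange(len(bmu)), bmu], 0.0)).mean())
                qe_trace.append(qe)

            counts = np.bincount(bmu, minlength=n_units).astype(np.float32)
            sums = np.zeros((n_units, X.shape[1]), dtype=np.float32)
            np.add.at(sums, bmu, X)
            H = np.exp(-grid_d2 / np.float32(2.0 * sigma**2))
            denom = H @ counts
            proto = (H @ sums) / denom[:, None]

        # final assignment against the last prototypes
        p_sq = (proto**2).sum(axis=1)
        d2 = x_sq[:, None] - 2.0 * (X @ proto.T) + p_sq[None, :]
        bmu = np.argmin(d2, axis=1)
        qe_trace.append(float(np.sqrt(np.maximum(d2[np.arange(len(bmu)), bmu], 0.0)).mean()))

        prototypes = pd.DataFrame(
            proto.astype(np.float64),
            index=pd.RangeIndex(n_units, name="metagene"),
            columns=self.matrix.samples,
        )
        return SOMResults(
            model=self,
            prototypes=prototypes,
            assignments=bmu,
            qe_trace=np.asarray(qe_trace),
        )


@dataclass
class SOMResults:
    """A fitted SOM portrayal.

    Attributes
    ----------
    prototypes : pandas.DataFrame
        (width*height) metagenes x samples; row i is the prototype profile
        of the pixel with linear index i (= row*width + col).
    assignments : numpy.ndarray
        Per-gene best-matching-unit linear index, aligned with
        ``model.matrix.genes``.
    qe_trace : numpy.ndarray
        Mean quantization error after each batch update (one entry per
        epoch); non-increasing over the annealing schedule.
    """

    model: SOMPortrayal
    prototypes: pd.DataFrame
    assignments: np.ndarray
    qe_trace: np.ndarray
    gene_index: dict = field(init=False)

    def __post_init__(self):
        self.gene_index = {g: i for i, g in enumerate(self.model.matrix.genes)}

    # -- convenience ---------------------------------------------------
    @property
    def width(self) -> int:
        return self.model.width

    @property
    def height(self) -> int:
        return self.model.height

    @property
    def samples(self) -> list[str]:
        return list(self.prototypes.columns)

    @property
    def n_metagenes(self) -> int:
        return len(self.prototypes)

    def gene_assignments(self) -> pd.Series:
        return pd.Series(self.assignments, index=self.model.matrix.genes, name="metagene")

    def genes_of_pixels(self, pixels) -> list[str]:
        """Genes whose best-matching unit lies in ``pixels`` (linear indices)."""
        pixels = set(int(p) for p in np.atleast_1d(np.asarray(pixels)).ravel())
        genes = self.model.matrix.genes
        return [g for g, b in zip(genes, self.assignments) if int(b) in pixels]

    # -- portraits -----------------------------------------------------
    def portrait(self, sample: str) -> np.ndarray:
        """The sample's metagene image, shape (height, width)."""
        if sample not in self.prototypes.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.prototypes[sample].to_numpy().reshape(self.height, self.width)

    def group_mean_portrait(self, samples) -> np.ndarray:
        """Pixelwise mean portrait over a nonempty sample group."""
        samples = list(samples)
        if not samples:
            raise ValueError("empty sample group")
        missing = [s for s in samples if s not in self.prototypes.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing[:5]}")
        return (
            self.prototypes[samples].mean(axis=1).to_numpy().reshape(self.height, self.width)
        )

    def difference_portrait(self, group_a, group_b) -> np.ndarray:
        """meanA - meanB, pixelwise."""
        return self.group_mean_portrait(group_a) - self.group_mean_portrait(group_b)

    # -- supporting maps ------------------------------------------------
    def population_map(self) -> np.ndarray:
        counts = np.bincount(self.assignments, minlength=self.n_metagenes)
        return counts.reshape(self.height, self.width)

    def variance_map(self, ddof: int = 1) -> np.ndarray:
        v = self.prototypes.to_numpy().var(axis=1, ddof=ddof)
        return v.reshape(self.height, self.width)

    def group_summary_map(self, labels: pd.Series) -> np.ndarray:
        """Pixelwise maximum over the group mean portraits."""
        labels = pd.Series(labels)
        groups = [self.group_mean_portrait(labels.index[labels == g]) for g in labels.unique()]
        return np.maximum.reduce(groups)

    def personalized_summary_map(self, q: float = 0.9) -> np.ndarray:
        """Pixelwise q-quantile over all individual portraits."""
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile q must be in (0, 1), got {q}")
        v = np.quantile(self.prototypes.to_numpy(), q, axis=1)
        return v.reshape(self.height, self.width)

    def supporting_maps(self, labels: pd.Series | None = None, q: float = 0.9) -> SupportingMaps:
        return SupportingMaps(
            variance=self.variance_map(),
            population=self.population_map(),
            group_summary=self.group_summary_map(labels) if labels is not None else None,
            personalized_summary=self.personalized_summary_map(q),
        )

    # -- sample similarity ----------------------------------------------
    def sample_distances(self) -> pd.DataFrame:
        """1 - Pearson correlation between sample metagene profiles."""
        corr = np.corrcoef(self.prototypes.to_numpy().T)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, 2.0)
        return pd.DataFrame(d, index=self.samples, columns=self.samples)

    def silhouette_scores(self, labels: pd.Series) -> pd.DataFrame:
        """Per-sample silhouette on 1-Pearson metagene-profile distances.

        Returns columns ``score`` (in [-1, 1]; 0 for singleton clusters) and
        ``nearest_other`` (the foreign cluster with smallest mean distance).
        """
        labels = pd.Series(labels).reindex(self.samples)
        if labels.isna().any():
            raise ValueError("labels must cover every sample")
        clusters = labels.unique()
        if len(clusters) < 2:
            raise ValueError("silhouette needs at least 2 clusters")
        d = self.sample_distances().to_numpy()
        lab = labels.to_numpy()
        scores = np.zeros(len(lab))
        nearest = np.empty(len(lab), dtype=object)
        for i in range(len(lab)):
            own = lab == lab[i]
            mean_foreign = {
                c: d[i, lab == c].mean() for c in clusters if c != lab[i]
            }
            nearest[i] = min(mean_foreign, key=lambda c: (mean_foreign[c], str(c)))
            if own.sum() <= 1:
                scores[i] = 0.0
                continue
            a = d[i, own].sum() / (own.sum() - 1)
            b = mean_foreign[nearest[i]]
            scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
        return pd.DataFrame({"score": scores, "nearest_other": nearest}, index=self.samples)

    def embed_samples(
        self,
        method: str = "ica",
        k: int = 2,
        seed: int = 0,
        correlation_threshold: float = 0.5,
    ):
        """Low-dimensional sample embedding or correlation network.

        ``method="ica"`` returns a samples x k DataFrame of independent
        components of the metagene profiles (zero-variance metagenes
        dropped); ``method="correlation-network"`` returns a networkx graph
        whose edges connect samples with metagene-profile Pearson
        correlation above ``correlation_threshold``.
        """
        P = self.prototypes.to_numpy().T  # samples x metagenes
        if method == "ica":
            if k > len(self.samples) - 1:
                raise ValueError(f"k={k} too large for {len(self.samples)} samples")
            keep = P.std(axis=0) > 0
            from sklearn.decomposition import FastICA

            ica = FastICA(n_components=k, random_state=seed, whiten="unit-variance", max_iter=1000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coords = ica.fit_transform(P[:, keep])
            return pd.DataFrame(
                coords, index=self.samples, columns=[f"IC{i + 1}" for i in range(k)]
            )
        if method == "correlation-network":
            import networkx as nx

            corr = np.corrcoef(P)
            g = nx.Graph()
            g.add_nodes_from(self.samples)
            n = len(self.samples)
            for i in range(n):
                for j in range(i + 1, n):
                    if corr[i, j] > correlation_threshold:
                        g.add_edge(self.samples[i], self.samples[j], weight=float(corr[i, j]))
            return g
        raise ValueError(f"unknown embedding method {method!r}")

    # -- spot access (delegates to spot_modules) -------------------------
    def detect_spots(
        self,
        summary: str = "group",
        labels: pd.Series | None = None,
        threshold_percentile: float = 86.0,
        min_pixels: int = 4,
        q: float = 0.9,
    ):
        """Detect overexpression spot modules on a summary map.

        ``summary`` selects the map: "group" (needs ``labels``) or
        "personalized" (q-quantile map).
        """
        from somscape.spot_modules import detect_spots

        if summary == "group":
            if labels is None:
                raise ValueError("group summary requires subtype labels")
            smap = self.group_summary_map(labels)
        elif summary == "personalized":
            smap = self.personalized_summary_map(q)
        else:
            raise ValueError(f"unknown summary map {summary!r}")
        return detect_spots(
            smap, model=self, threshold_percentile=threshold_percentile, min_pixels=min_pixels
        )

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Write a single portable .npz archive (versioned layout)."""
        meta = {
            "format": "somscape-som",
            "version": 1,
            "width": self.width,
            "height": self.height,
            "epochs": self.model.epochs,
            "seed": self.model.seed,
            "sigma_start": self.model.sigma_start,
            "sigma_end": self.model.sigma_end,
        }
        np.savez_compressed(
            path,
            prototypes=self.prototypes.to_numpy(),
            assignments=self.assignments,
            qe_trace=self.qe_trace,
            samples=np.array(self.samples, dtype=object),
            genes=np.array(self.model.matrix.genes, dtype=object),
            matrix=self.model.matrix.values.to_numpy(),
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path) -> "SOMResults":
        with np.load(path, allow_pickle=True) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("format") != "somscape-som":
                raise ValueError(f"{path}: not a somscape SOM archive")
            genes = list(z["genes"])
            samples = list(z["samples"])
            matrix = ExpressionMatrix(
                pd.DataFrame(z["matrix"], index=genes, columns=samples), scale="centralized"
            )
            model = SOMPortrayal(
                matrix,
                grid=(meta["width"], meta["height"]),
                epochs=meta["epochs"],
                seed=meta["seed"],
                sigma_start=meta["sigma_start"],
                sigma_end=meta["sigma_end"],
            )
            return cls(
                model=model,
                prototypes=pd.DataFrame(
                    z["prototypes"], index=pd.RangeIndex(meta["width"] * meta["height"]),
                    columns=samples,
                ),
                assignments=z["assignments"],
                qe_trace=z["qe_trace"],
            )

    def summary(self) -> str:
        """Human-readable fit summary."""
        pop = self.population_map()
        lines = [
            "SOM portrayal results",
            "=====================",
            f"grid:              {self.width} x {self.height} ({self.n_metagenes} metagenes)",
            f"genes:             {len(self.assignments)}",
            f"samples:           {len(self.samples)}",
            f"epochs:            {self.model.epochs}",
            f"final quant. err.: {self.qe_trace[-1]:.4f}",
            f"occupied pixels:   {(pop > 0).sum()} / {self.n_metagenes}",
            f"max genes / pixel: {pop.max()}",
        ]
        return "\n".join(lines)
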