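"""Synthetic multi-lesion tumor cohorts with planted co-expression modules.

The generator emulates the statistical structure the portrayal pipeline
assumes for a liver-metastasis style cohort:

* centralized-log10-scale expression with a handful of planted
  co-expression modules (100-600 genes each) activated subtype-specifically;
* five tumor subtypes plus a small liver-tissue-like ("LIV") group;
* a dedicated liver-contamination module additionally activated in a
  configurable fraction of samples of every subtype;
* survival hazard exponentially linked to planted module activations;
* several lesions per patient, with intra-patient noise much smaller than
  the inter-patient spread.

Every quantity the pipeline later estimates (module gene lists, subtype
markers, contamination flags, log-hazards) is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from somscape.preprocessing import ExpressionMatrix
from somscape.geneset_analysis import GeneSetCollection

BACKGROUND = ""  # module label of unplanted genes


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``levels`` maps subtype label -> activation in centralized-log10 units;
    subtypes not listed get 0.
    """

    label: str
    n_genes: int
    levels: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortDesign:
    """Full parameterization of a synthetic cohort."""

    n_genes: int
    n_samples: int
    subtype_proportions: dict[str, float]
    modules: list[ModuleSpec]
    contamination_module: str | None = None
    contamination_fraction: float = 0.0
    contamination_level: float = 0.0
    noise_sd: float = 0.25
    intra_patient_sd: float = 0.05
    lesions_per_patient: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    survival_betas: dict[str, float] = field(default_factory=dict)
    censor_fraction: float = 0.3
    baseline_hazard: float = np.log(2) / 24.0  # median ~24 time units at act=0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, expected 1")
        labels = [m.label for m in self.modules]
        if len(set(labels)) != len(labels):
            raise ValueError("module labels must be unique")
        if sum(m.n_genes for m in self.modules) > self.n_genes:
            raise ValueError(
                f"module gene counts ({sum(m.n_genes for m in self.modules)}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if any(m.n_genes <= 0 for m in self.modules):
            raise ValueError("module gene counts must be positive")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ValueError("censor_fraction must be in [0, 1]")
        if self.contamination_module is not None and self.contamination_module not in labels:
            raise ValueError(f"contamination module {self.contamination_module!r} not planted")
        if abs(sum(self.lesions_per_patient.values()) - 1.0) > 1e-9:
            raise ValueError("lesions_per_patient probabilities must sum to 1")
        known = set(labels)
        unknown = set(self.survival_betas) - known
        if unknown:
            raise ValueError(f"survival_betas reference unknown modules: {sorted(unknown)}")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort.

    Attributes
    ----------
    gene_modules : pandas.Series
        gene ID -> module label ("" for background genes).
    sample_info : pandas.DataFrame
        One row per sample: subtype, patient, contaminated flag, per-module
        activation columns ``act_<label>``, and ``log_hazard`` (relative to
        baseline; 0 until survival is attached, if no betas).
    design : CohortDesign
    """

    gene_modules: pd.Series
    sample_info: pd.DataFrame
    design: CohortDesign

    def module_genes(self, label: str) -> list[str]:
        return list(self.gene_modules.index[self.gene_modules == label])

    @property
    def module_labels(self) -> list[str]:
        return [m.label for m in self.design.modules]

    def activation(self, label: str) -> pd.Series:
        return self.sample_info[f"act_{label}"]

    def as_gmt(self) -> GeneSetCollection:
        sets = {m.label: self.module_genes(m.label) for m in self.design.modules}
        descs = {m.label: f"planted module {m.label}" for m in self.design.modules}
        return GeneSetCollection(sets, descriptions=descs)


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    """The cohort design shipped with the package (data/default_design.yaml).

    Six planted modules of 150-400 genes across 6000 genes and 120 samples:
    five subtype-marker modules (A-E) and a liver module (F) active in the
    LIV group and, additively, in 35% of samples of every subtype. Module A
    carries a +0.7 log-hazard and module E a -0.7 log-hazard, mirroring a
    risk and a protective expression program.
    """
    text = resources.files("somscape").joinpath("data/default_design.yaml").read_text()
    return design_from_dict(yaml.safe_load(text), seed=seed, **overrides)


def design_from_dict(cfg: dict, seed: int | None = None, **overrides) -> CohortDesign:
    """Build a CohortDesign from a plain dict (e.g. parsed YAML)."""
    cfg = dict(cfg)
    modules = [
        ModuleSpec(label=m["label"], n_genes=int(m["n_genes"]), levels=dict(m.get("levels", {})))
        for m in cfg.pop("modules")
    ]
    lesions = {int(k): float(v) for k, v in cfg.pop("lesions_per_patient").items()}
    if seed is not None:
        cfg["seed"] = seed
    cfg.update(overrides)
    design = CohortDesign(modules=modules, lesions_per_patient=lesions, **cfg)
    design.validate()
    return design


def generate_cohort(
    design: CohortDesign,
) -> tuple[ExpressionMatrix, CohortTruth, pd.DataFrame]:
    """Draw one cohort.

    Returns the expression matrix (centralized-log10 scale up to the planted
    mean shifts), the ground truth, and the sample annotation table
    (columns sample, subtype, patient). Deterministic under ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    subtypes = list(design.subtype_proportions)
    probs = np.array([design.subtype_proportions[s] for s in subtypes])
    lesion_counts = np.array(sorted(design.lesions_per_patient))
    lesion_probs = np.array([design.lesions_per_patient[k] for k in lesion_counts])

    # patients are drawn until n_samples lesions accumulate; all lesions of a
    # patient share its subtype
    patient_subtype: list[str] = []
    patient_lesions: list[int] = []
    total = 0
    while total < design.n_samples:
        patient_subtype.append(subtypes[rng.choice(len(subtypes), p=probs)])
        k = int(rng.choice(lesion_counts, p=lesion_probs))
        k = min(k, design.n_samples - total)
        patient_lesions.append(k)
        total += k

    sample_ids, patients, sample_subtype = [], [], []
    for p, (sub, k) in enumerate(zip(patient_subtype, patient_lesions)):
        pid = f"P{p + 1:03d}"
        for lesion in range(k):
            sample_ids.append(f"{pid}_L{lesion + 1}")
            patients.append(pid)
            sample_subtype.append(sub)
    n = design.n_samples

    contaminated = rng.random(n) < design.contamination_fraction

    # per-sample module activations
    labels = [m.label for m in design.modules]
    act = np.zeros((len(labels), n))
    for i, m in enumerate(design.modules):
        act[i] = [m.levels.get(s, 0.0) for s in sample_subtype]
        if m.label == design.contamination_module:
            act[i] += np.where(contaminated, design.contamination_level, 0.0)

    # gene -> module assignment: modules take leading blocks, rest background
    gene_ids = [f"G{g + 1:05d}" for g in range(design.n_genes)]
    gene_module = np.full(design.n_genes, BACKGROUND, dtype=object)
    pos = 0
    for m in design.modules:
        gene_module[pos : pos + m.n_genes] = m.label
        pos += m.n_genes

    # signal per gene/sample
    expr = np.zeros((design.n_genes, n))
    for i, m in enumerate(design.modules):
        expr[gene_module == m.label] = act[i]

    # patient-level biological noise + lesion-level intra-patient noise
    n_patients = len(patient_subtype)
    patient_idx = pd.Categorical(patients, categories=[f"P{p + 1:03d}" for p in range(n_patients)]).codes
    if design.noise_sd > 0:
        patient_noise = rng.normal(0.0, design.noise_sd, size=(design.n_genes, n_patients))
        expr += patient_noise[:, patient_idx]
    if design.intra_patient_sd > 0:
        expr += rng.normal(0.0, design.intra_patient_sd, size=(design.n_genes, n))

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids), scale="log10"
    )

    info = pd.DataFrame(
        {
            "sample": sample_ids,
            "subtype": sample_subtype,
            "patient": patients,
            "contaminated": contaminated,
        }
    ).set_index("sample")
    for i, lab in enumerate(labels):
        info[f"act_{lab}"] = act[i]
    info["log_hazard"] = sum(
        design.survival_betas.get(lab, 0.0) * act[i] for i, lab in enumerate(labels)
    )

    truth = CohortTruth(
        gene_modules=pd.Series(gene_module, index=gene_ids, name="module"),
        sample_info=info,
        design=design,
    )
    annotation = info.reset_index()[["sample", "subtype", "patient"]]
    return matrix, truth, annotation


def attach_survival(
    truth: CohortTruth,
    betas: dict[str, float] | None = None,
    censor_fraction: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw exponential survival with rate proportional to exp(sum beta*act).

    Censoring is an independent exponential clock whose rate is chosen so
    the expected censored fraction matches ``censor_fraction``
    (``censor_fraction=0`` means no censoring at all). Returns a table with
    columns sample, patient, os_time, event.
    """
    design = truth.design
    if len(truth.sample_info) == 0:
        raise ValueError("empty cohort: no samples to attach survival to")
    if betas is None:
        betas = design.survival_betas
    unknown = set(betas) - set(truth.module_labels)
    if unknown:
        raise ValueError(f"betas reference unknown modules: {sorted(unknown)}")
    if censor_fraction is None:
        censor_fraction = design.censor_fraction
    if seed is None:
        seed = design.seed + 1
    rng = np.random.default_rng(seed)

    log_hazard = np.zeros(len(truth.sample_info))
    for lab, beta in betas.items():
        log_hazard = log_hazard + beta * truth.activation(lab).to_numpy()
    rate = design.baseline_hazard * np.exp(log_hazard)
    event_time = rng.exponential(1.0 / rate)
    if censor_fraction > 0:
        cens_rate = rate.mean() * censor_fraction / (1.0 - censor_fraction)
        censor_time = rng.exponential(1.0 / cens_rate, size=len(rate))
    else:
        censor_time = np.full(len(rate), np.inf)
    os_time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    truth.sample_info["log_hazard"] = log_hazard
    return pd.DataFrame(
        {
            "sample": truth.sample_info.index,
            "patient": truth.sample_info["patient"].to_numpy(),
            "os_time": os_time,
            "event": event,
        }
    )


def write_cohort(
    outdir,
    matrix: ExpressionMatrix,
    truth: CohortTruth,
    survival: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write expression/annotation/survival TSVs and the truth GMT.

    Returns a dict of the written paths. Files round-trip losslessly through
    the package readers.
    """
    from pathlib import Path

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"expression": str(outdir / "expression.tsv")}
        matrix.to_tsv(paths["expression"])
        paths["annotation"] = str(outdir / "annotation.tsv")
        truth.sample_info.reset_index()[["sample", "subtype", "patient"]].to_csv(
            paths["annotation"], sep="\t", index=False
        )
        if survival is not None:
            paths["survival"] = str(outdir / "survival.tsv")
            survival.to_csv(paths["survival"], sep="\t", index=False)
        paths["modules"] = str(outdir / "true_modules.gmt")
        truth.as_gmt().to_gmt(paths["modules"])
    except OSError as exc:
        raise OSError(f"failed writing cohort under {outdir}: {exc}") from exc
    return paths


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV (columns sample, subtype, patient)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "subtype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df


def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV (columns sample, os_time, event)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "os_time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing survival columns {sorted(missing)}")
    if (df["os_time"] <= 0).any():
        bad = df.loc[df["os_time"] <= 0, "sample"].iloc[0]
        raise ValueError(f"{path}: non-positive survival time for sample {bad!r}")
    return df


def gradient_design(
    n_genes: int = 1500,
    n_samples: int = 100,
    seed: int = 0,
    noise_sd: float = 0.25,
    gradient_span: float = 2.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """A one-dimensional cohort: one module's activation rises linearly.

    Used to test trajectory recovery. Returns the expression matrix and the
    planted position in [0, 1] per sample. The gradient module occupies the
    first 300 genes; a second, anti-correlated module (next 300) falls
    linearly, so the leading principal components trace the gradient.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.random(n_samples))
    expr = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    expr[:300] += gradient_span * (pos - 0.5)
    expr[300:600] -= gradient_span * (pos - 0.5)
    ids = [f"G{g + 1:05d}" for g in range(n_genes)]
    cols = [f"S{i + 1:03d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(pd.DataFrame(expr, index=ids, columns=cols), scale="log10")
    return matrix, pd.Series(pos, index=cols, name="position")
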