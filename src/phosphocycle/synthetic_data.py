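"""Synthetic poly-transfection flow-cytometry event generator.

Emulates the statistical structure of poly-transfected mammalian cells
measured by flow cytometry, so every downstream analysis stage is
testable without instrument data:

* per-complex plasmid dosages are log-normal in log10 space (``dex``),
  with a shared per-cell "transfectability" factor correlating the
  complexes, and an untransfected subpopulation at zero dosage;
* per-cell outputs are rendered at steady state from the covalent
  modification cycle model (single-timepoint snapshots, as in 48 h
  measurements): open loop (OL) with a constitutively expressed
  phosphatase, or closed loop (CL) with the phosphatase co-transcribed
  with the output;
* cell-type-specific miRNA activity knocks down production of plasmids
  carrying matching target sites (e.g. miR-21 sites on the phosphatase
  in HeLa-like cells);
* perturbations act either post-transcriptionally (a fold-knockdown w of
  output/phosphatase production) or via transcriptional-resource loading
  (a factor scaling the production rate alpha);
* measured channels carry multiplicative log-normal measurement noise
  plus additive Gaussian autofluorescence, so a fraction of events is
  non-positive, exercising the pipeline's discard rules.

Event tables are plain pandas DataFrames (one row per cell) with
fluorescence channels in MEFL-like linear units plus ground-truth
metadata columns; they round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cmc_model import CMCParams, PromoterHill, _gk_quadratic, closedloop_output

__all__ = [
    "Complex",
    "TransfectionDesign",
    "CellTypeProfile",
    "PerturbationSpec",
    "sample_dosages",
    "render_events",
    "write_events",
    "read_events",
    "default_cmc_template",
    "feedback_design",
    "classifier_design",
    "hela_profile",
    "hek_profile",
    "neutral_profile",
    "feedback_experiment",
    "classifier_experiment",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("cell_type", "topology", "perturbation_level", "seed")


@dataclass(frozen=True)
class Complex:
    """One DNA-lipid complex: plasmid weights, marker channel, dosage law."""

    name: str
    weights: Mapping[str, float]
    marker_channel: str
    median_dex: float = 4.0  # log10 median dosage in MEFL-like units
    sd_dex: float = 0.8

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.weights.values()):
            raise ValueError("plasmid weights must be >= 0")
        if self.sd_dex < 0:
            raise ValueError("sd_dex must be >= 0")


@dataclass(frozen=True)
class TransfectionDesign:
    complexes: Sequence[Complex]
    transfectability_sd_dex: float = 0.4
    untransfected_fraction: float = 0.3
    autofluorescence_mean: float = 100.0
    autofluorescence_sd: float = 50.0
    measurement_cv: float = 0.25
    # plasmid name -> miRNA names whose target sites sit in its UTRs
    target_sites: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.complexes) < 1:
            raise ValueError("need at least one complex")
        if not 0.0 <= self.untransfected_fraction <= 1.0:
            raise ValueError("untransfected_fraction must lie in [0, 1]")
        if self.measurement_cv < 0 or self.transfectability_sd_dex < 0:
            raise ValueError("noise parameters must be >= 0")

    def complex_named(self, name: str) -> Complex:
        for c in self.complexes:
            if c.name == name:
                return c
        raise KeyError(f"no complex named {name!r}")

    def plasmid_dosage(self, plasmid: str, dosages: np.ndarray) -> np.ndarray:
        """Per-cell dosage of one plasmid, summed over complexes carrying it."""
        total = np.zeros(dosages.shape[0])
        for j, c in enumerate(self.complexes):
            w = c.weights.get(plasmid, 0.0)
            if w:
                total = total + w * dosages[:, j]
        return total


@dataclass(frozen=True)
class CellTypeProfile:
    """miRNA activity of a cell type: retained fraction per miRNA.

    A retained fraction of 1 means the miRNA is absent (or the transcript
    carries no matching sites); 0 means complete knockdown.  ``scale``
    multiplies all dosage-derived production, modelling cell-type-specific
    expression strength.
    """

    name: str
    mirna_activity: Mapping[str, float] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("expression scale must be > 0")
        for m, r in self.mirna_activity.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retained fraction for {m!r} must lie in [0, 1]")

    def retained(self, sites: tuple[str, ...]) -> float:
        out = 1.0
        for m in sites:
            out *= self.mirna_activity.get(m, 1.0)
        return out


@dataclass(frozen=True)
class PerturbationSpec:
    """Dose-to-effect map for a perturbation complex.

    ``post_transcriptional``: effect(level) is a knockdown fraction
    w in [0, 1) of output/phosphatase production (e.g. miR-FF4 cleaving
    TFF4 sites).  ``resource_loading``: effect(level) is a factor in
    (0, 1] multiplying the production rate alpha (e.g. Gal4-VPR
    sequestering transcriptional resources).  Zero dose gives no effect.
    """

    kind: str  # "post_transcriptional" | "resource_loading"
    effect: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if self.kind not in ("post_transcriptional", "resource_loading"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    def production_factor(self, level) -> np.ndarray:
        """Multiplicative production factor (1 - w, or the resource factor)."""
        level = np.asarray(level, dtype=float)
        eff = np.asarray(self.effect(level), dtype=float)
        if self.kind == "post_transcriptional":
            if np.any((eff < 0) | (eff >= 1)):
                raise ValueError("knockdown w must lie in [0, 1)")
            fac = 1.0 - eff
        else:
            if np.any((eff <= 0) | (eff > 1)):
                raise ValueError("resource factor must lie in (0, 1]")
            fac = eff
        return np.where(level == 0.0, 1.0, fac)

    @classmethod
    def constant_knockdown(cls, w: float) -> "PerturbationSpec":
        return cls("post_transcriptional", lambda lv: np.full_like(np.asarray(lv, float), w))

    @classmethod
    def hill_knockdown(cls, w_max: float, K_half: float, n: float = 1.0) -> "PerturbationSpec":
        def eff(lv):
            lv = np.asarray(lv, dtype=float)
            return w_max * lv**n / (K_half**n + lv**n)
        return cls("post_transcriptional", eff)

    @classmethod
    def resource_loading(cls, lam: float) -> "PerturbationSpec":
        """alpha -> alpha / (1 + lam * G): simplest saturating competition."""
        def eff(lv):
            lv = np.asarray(lv, dtype=float)
            return 1.0 / (1.0 + lam * lv)
        return cls("resource_loading", eff)


# ---------------------------------------------------------------------------
# Sampling and rendering
# ---------------------------------------------------------------------------

def sample_dosages(design: TransfectionDesign, n_cells: int, seed: int) -> np.ndarray:
    """Per-cell plasmid-complex dosages, (n_cells x n_complexes).

    dosage = 10 ** (shared transfectability factor + complex-specific
    normal draw), with the untransfected fraction zeroed across all
    complexes.  Bit-identical for identical (design, n_cells, seed).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    shared = rng.normal(0.0, design.transfectability_sd_dex, size=n_cells)
    cols = []
    for c in design.complexes:
        draw = rng.normal(c.median_dex, c.sd_dex, size=n_cells)
        cols.append(10.0 ** (shared + draw))
    dosages = np.column_stack(cols)
    untransfected = rng.random(n_cells) < design.untransfected_fraction
    dosages[untransfected, :] = 0.0
    return dosages


def default_cmc_template() -> CMCParams:
    """CMC parameter template used to render per-cell outputs.

    Chosen so that typical transfected cells operate near the
    quasi-integral regime: substrate in excess of the kinase Michaelis
    constant (X_t = 1000 >> K_Mk = 1), saturated phosphatase
    (K_Mp = 1 << typical X*), and an unsaturated promoter (K_D = 500
    with alpha large enough that phi stays ~0.01 at the operating
    point).  K_t and alpha are placeholders, replaced per cell.
    """
    return CMCParams(
        theta_k=1.0, theta_p=1.0, K_Mk=1.0, K_Mp=1.0,
        X_t=1000.0, K_t=100.0, alpha=1e4, gamma=1.0,
        phi=PromoterHill(K_D=500.0, basal=0.0), rho=1.0, w=0.0,
    )


def render_events(
    dosages: np.ndarray,
    design: TransfectionDesign,
    cmc: CMCParams,
    cell_type: CellTypeProfile,
    perturbation: PerturbationSpec | None,
    topology: str,
    seed: int,
    *,
    kinase_potency: float = 0.01,
    phosphatase_potency: float = 0.05,
    basal_phosphatase: float = 1.0,
    alpha_per_dosage: float = 1.0,
    output_gain: float = 50.0,
    output_channel: str = "output",
    perturbation_complex: str = "perturbation",
) -> pd.DataFrame:
    """Render a per-cell event table from sampled dosages.

    Per cell: K_t = kinase_potency * kinase dosage; phosphatase
    production scales with its dosage times the miRNA retained fraction;
    X_t is held constant (idealised endoRNase feedforward on OmpR-VP64).
    OL: the phosphatase level is set by its own constitutive expression
    (plus a small background dephosphorylation activity), X* comes from
    the cycle transfer curve, and the output is the steady state of its
    own production.  CL: the output/phosphatase pair is co-transcribed
    with alpha scaled by the output-plasmid dosage, and the output is the
    closed-loop fixed point.  Perturbations enter as a knockdown w or a
    resource factor on production.  Markers scale with complex dosage;
    all measured channels get multiplicative log-normal noise plus
    additive autofluorescence (values may be non-positive).
    """
    if topology not in ("OL", "CL"):
        raise ValueError(f"topology must be OL|CL, got {topology!r}")
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != len(design.complexes):
        raise ValueError("dosage matrix shape does not match the design")
    n = dosages.shape[0]
    rng = np.random.default_rng(seed)
    scale = cell_type.scale

    dos_kin = design.plasmid_dosage("kinase", dosages)
    dos_phos = design.plasmid_dosage("phosphatase", dosages)
    dos_out = design.plasmid_dosage("output", dosages)
    if not (np.any(dos_kin) or np.any(dos_out)):
        raise ValueError("design provides neither a 'kinase' nor an 'output' plasmid")

    retained_phos = cell_type.retained(tuple(design.target_sites.get("phosphatase", ())))
    retained_out = cell_type.retained(tuple(design.target_sites.get("output", ())))

    # perturbation dosage level (zero when no perturbation complex present)
    level = np.zeros(n)
    if perturbation is not None:
        names = [c.name for c in design.complexes]
        if perturbation_complex in names:
            level = dosages[:, names.index(perturbation_complex)]
        else:
            level = np.ones(n)  # no dedicated complex: unit level, the map decides
        f_pert = perturbation.production_factor(level)
    else:
        f_pert = np.ones(n)

    K_t = kinase_potency * dos_kin * scale

    if topology == "OL":
        # constitutive phosphatase from its own complex; perturbation
        # targets the output mRNA only
        P_t = basal_phosphatase + phosphatase_potency * dos_phos * retained_phos * scale
        X_star = _gk_quadratic(
            cmc.theta_k, cmc.theta_p, cmc.K_Mk, cmc.K_Mp, cmc.X_t, K_t, P_t,
        )
        alpha_cell = alpha_per_dosage * dos_out * retained_out * scale * f_pert
        Y = cmc.rho * alpha_cell * np.asarray(cmc.phi(X_star)) / cmc.gamma
    else:
        # feedback: output 2A-linked to the phosphatase, alpha from the
        # output-plasmid dosage; knockdown and resource loading fold into
        # the disturbance w on the shared transcript
        alpha_cell = alpha_per_dosage * dos_out * scale
        f_prod = f_pert * retained_out * retained_phos
        w_eff = np.clip(1.0 - f_prod, 0.0, 1.0 - 1e-12)
        Y = closedloop_output(cmc, K_t, alpha_cell, w_eff)

    def measure(signal):
        sigma = np.sqrt(np.log1p(design.measurement_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
        auto = rng.normal(design.autofluorescence_mean, design.autofluorescence_sd, size=n)
        return signal * noise + auto

    data = {}
    for j, c in enumerate(design.complexes):
        data[c.marker_channel] = measure(dosages[:, j] * scale)
    data[output_channel] = measure(Y * output_gain)

    df = pd.DataFrame(data)
    for j, c in enumerate(design.complexes):
        df[f"dosage_{c.name}"] = dosages[:, j]
    df["cell_type"] = cell_type.name
    df["topology"] = topology
    df["perturbation_level"] = level
    df["seed"] = seed
    return df


def write_events(table: pd.DataFrame, path) -> None:
    """Write an event table as delimited text (CSV with header)."""
    if not isinstance(table, pd.DataFrame):
        raise TypeError("table must be a DataFrame")
    table.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Ready-made study designs
# ---------------------------------------------------------------------------

def neutral_profile(name: str = "HEK") -> CellTypeProfile:
    return CellTypeProfile(name=name)


def hek_profile() -> CellTypeProfile:
    """HEK-293-like: miR-21 essentially inactive."""
    return CellTypeProfile(name="HEK", mirna_activity={"miR-21": 1.0})


def hela_profile(mir21_retained: float = 0.05) -> CellTypeProfile:
    """HeLa-like: high miR-21 activity knocks matching transcripts down."""
    return CellTypeProfile(name="HeLa", mirna_activity={"miR-21": mir21_retained})


def feedback_design(
    output_weight: float = 1.0,
    with_perturbation: bool = False,
    **kwargs,
) -> TransfectionDesign:
    """Kinase complex + output/controller complex (+ optional perturbation).

    ``output_weight`` scales the output-plasmid copy number, mirroring the
    reduced-copy OL comparison variants (1, 1/3, 1/9, 1/27, 1/81).
    """
    complexes = [
        Complex("kinase", {"kinase": 1.0}, "K_marker"),
        Complex("controller", {"output": output_weight}, "O_marker"),
    ]
    if with_perturbation:
        complexes.append(Complex("perturbation", {"perturb": 1.0}, "G_marker"))
    return TransfectionDesign(complexes=complexes, **kwargs)


def classifier_design(variant: str = "T21", output_weight: float = 0.5, **kwargs) -> TransfectionDesign:
    """miRNA-sensor circuit: kinase, constitutive phosphatase, output.

    The phosphatase transcript carries miR-21 target sites (T21 variant)
    or inert miR-FF4 sites (TFF4 control); plasmid ratio defaults to
    1 : 1 : 0.5 kinase : phosphatase : output.
    """
    if variant not in ("T21", "TFF4"):
        raise ValueError(f"variant must be T21|TFF4, got {variant!r}")
    sites = ("miR-21",) if variant == "T21" else ("miR-FF4",)
    return TransfectionDesign(
        complexes=[
            Complex("kinase", {"kinase": 1.0}, "K_marker"),
            Complex("phosphatase", {"phosphatase": 1.0}, "P_marker"),
            Complex("output", {"output": output_weight}, "O_marker"),
        ],
        target_sites={"phosphatase": sites},
        **kwargs,
    )


def feedback_experiment(
    n_cells: int,
    seed: int,
    topology: str,
    output_weight: float = 1.0,
    perturbation: PerturbationSpec | None = None,
    cmc: CMCParams | None = None,
    **render_kwargs,
) -> pd.DataFrame:
    """One rendered OL/CL feedback sample under the default study conditions."""
    design = feedback_design(output_weight=output_weight)
    dosages = sample_dosages(design, n_cells, seed)
    return render_events(
        dosages, design, cmc or default_cmc_template(), neutral_profile("HEK-293FT"),
        perturbation, topology, seed + 1, **render_kwargs,
    )


def classifier_experiment(
    n_cells: int,
    seed: int,
    variant: str = "T21",
    cell_type: CellTypeProfile | None = None,
    cmc: CMCParams | None = None,
    **render_kwargs,
) -> pd.DataFrame:
    """One rendered miRNA-sensor sample (open-loop constitutive phosphatase)."""
    design = classifier_design(variant=variant)
    dosages = sample_dosages(design, n_cells, seed)
    return render_events(
        dosages, design, cmc or default_cmc_template(),
        cell_type or hela_profile(), None, "OL", seed + 1, **render_kwargs,
    )
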