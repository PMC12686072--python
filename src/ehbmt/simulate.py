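"""Synthetic cohort generator.

Emulates the statistical structure the typing method is designed for, at the
normalized-expression level (Gaussian, not counts — the classifier consumes
normalized values, and the Gaussian model keeps expectations closed-form):

* three latent EMT states (epithelial / hybrid / mesenchymal) with panel
  means separated by ``separation``; epithelial and mesenchymal sub-panels
  anti-coupled in normal tissue (mesenchymal mean = -epithelial mean).
  Marker strengths carry fixed per-gene loadings (mean 1), and the hybrid
  state is a distinct mosaic partial-EMT program: each marker is either
  retained or lost (gene-specific sign, mean 0), so hybrids co-express
  both marker sets at intermediate panel-mean scores while occupying their
  own full-amplitude direction in marker space — without gene-level
  structure all three states collapse onto the single
  epithelial-vs-mesenchymal contrast axis under correlation distance and
  only two clusters are recoverable,
* tumor tissue adds a shared per-sample upregulation offset to BOTH
  sub-panels (mean ``tumor_offset``, sd ``tumor_shared_sd``), jointly
  upregulating the markers and decoupling the epithelial-mesenchymal
  anti-correlation seen in normal tissue,
* paired designs draw the tumor state from a row-stochastic transition
  matrix conditioned on the normal state,
* survival times are exponential with subtype-specific hazards and uniform
  right censoring,
* single-cell count tables are multinomial with a lower epithelial fraction
  in tumors.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleTable
from .panels import GenePanel, default_panel
from .stats import SUBTYPE_ORDER

__all__ = [
    "SimulationParams",
    "simulate_cohort",
    "simulate_paired_cohort",
    "simulate_cell_counts",
]

# per-subtype exponential hazards (per month) matching 5-year survival of
# roughly 59% / 55% / 38% for the epithelial / hybrid / mesenchymal states
_DEFAULT_HAZARDS = (0.00876, 0.01012, 0.01595)

_DEFAULT_TRANSITION = (
    (0.20, 0.50, 0.30),  # normal EPC -> mostly hybrid/mesenchymal tumor
    (0.10, 0.60, 0.30),
    (0.05, 0.35, 0.60),
)

_DEFAULT_CELL_PROPORTIONS = {
    "normal": {"epithelial": 0.45, "fibroblast": 0.15, "endothelial": 0.10, "immune": 0.30},
    "tumor": {"epithelial": 0.20, "fibroblast": 0.25, "endothelial": 0.15, "immune": 0.40},
}


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters for the synthetic cohorts.

    ``separation`` is the latent-state panel mean in z-score-like units
    (+a / 0 / -a for the epithelial sub-panel across the three states);
    ``noise_sd`` the per-gene Gaussian noise; ``tumor_offset`` and
    ``tumor_shared_sd`` the mean and spread of the shared tumor
    upregulation. Prevalence defaults follow the normal-vs-tumor subtype
    shift the method is meant to expose (epithelial-dominant normal tissue,
    hybrid-dominant tumors).
    """

    n_samples: int = 300
    n_pairs: int = 100
    prevalence_normal: tuple = (0.60, 0.10, 0.30)
    prevalence_tumor: tuple = (0.35, 0.43, 0.22)
    separation: float = 1.0
    noise_sd: float = 0.5
    tumor_offset: float = 1.0
    tumor_shared_sd: float = 0.8
    n_background: int = 200
    transition: tuple = _DEFAULT_TRANSITION
    hazards: tuple = _DEFAULT_HAZARDS
    censor_horizon: float = 120.0  # months; censoring ~ Uniform(0, horizon)
    cell_proportions: dict = field(default_factory=lambda: _DEFAULT_CELL_PROPORTIONS)
    cells_per_sample: int = 1000
    panel: GenePanel = field(default_factory=default_panel)

    def __post_init__(self):
        for name in ("prevalence_normal", "prevalence_tumor"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 3 nonnegative values summing to 1")
        T = np.asarray(self.transition, dtype=float)
        if T.shape != (3, 3) or (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 3x3 row-stochastic")
        if self.noise_sd <= 0 or self.separation <= 0:
            raise ValueError("noise_sd and separation must be positive")

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def _state_signatures(rng, params: SimulationParams) -> np.ndarray:
    """Per-gene panel means for the three states; shape (3, n_panel_genes).

    Each marker gets a fixed strength loading w_g ~ U(0.7, 1.3), so the
    epithelial-state epithelial mean is +a on average (and -a for the
    mesenchymal state), anti-coupled across the two sub-panels. The hybrid
    state follows its own mosaic partial-EMT program rho_g ∈ {-1, +1}: each
    marker is either retained or lost with equal probability, so the panel-
    average hybrid scores are intermediate (≈ 0) while the state keeps full
    per-gene amplitude — a weaker (sub-amplitude) hybrid program collapses
    toward the epithelial-mesenchymal contrast axis once the cohort is
    gene-centered, and the three states stop being separable.
    """
    a = params.separation
    n_e = len(params.panel.epithelial)
    n_m = len(params.panel.mesenchymal)
    w = rng.uniform(0.7, 1.3, size=n_e + n_m)
    rho = rng.choice([-1.0, 1.0], size=n_e + n_m)
    axis = np.concatenate([np.ones(n_e), -np.ones(n_m)])  # epi +, mes -
    epc = a * w * axis
    hpc = a * w * rho
    mpc = -a * w * axis
    return np.vstack([epc, hpc, mpc])


def _expression_profile(
    rng, params: SimulationParams, signatures: np.ndarray, state: int, tumor: bool
) -> np.ndarray:
    shared = rng.normal(params.tumor_offset, params.tumor_shared_sd) if tumor else 0.0
    panel_vals = rng.normal(signatures[state] + shared, params.noise_sd)
    bg = rng.normal(0.0, params.noise_sd, size=params.n_background)
    return np.concatenate([panel_vals, bg])


def _gene_index(params: SimulationParams) -> list:
    bg = [f"BG{i:04d}" for i in range(params.n_background)]
    return list(params.panel.all_genes) + bg


def _survival(rng, params: SimulationParams, states: np.ndarray):
    hazards = np.asarray(params.hazards, dtype=float)
    event_t = rng.exponential(1.0 / hazards[states])
    censor_t = rng.uniform(0.0, params.censor_horizon, size=states.size)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return time, event


def simulate_cohort(
    params: SimulationParams | None = None, seed: int = 42, tissue: str = "tumor"
):
    """Simulate an unpaired cohort.

    Returns ``(ExpressionMatrix, SampleTable, true_labels)`` where
    ``true_labels`` is a Series of planted subtypes (EPC/HPC/MPC) indexed by
    sample id. ``tissue`` selects the prevalence vector and whether the
    shared tumor upregulation applies.
    """
    params = params or SimulationParams()
    if tissue not in ("normal", "tumor"):
        raise ValueError("tissue must be 'normal' or 'tumor'")
    rng = np.random.default_rng(seed)
    prev = params.prevalence_tumor if tissue == "tumor" else params.prevalence_normal
    signatures = _state_signatures(rng, params)
    states = rng.choice(3, size=params.n_samples, p=np.asarray(prev, dtype=float))
    sample_ids = [f"S{i:04d}" for i in range(params.n_samples)]
    X = np.column_stack(
        [_expression_profile(rng, params, signatures, s, tissue == "tumor") for s in states]
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=_gene_index(params), columns=sample_ids),
        normalized="log",
    )
    time, event = _survival(rng, params, states)
    meta = SampleTable(
        data=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": [f"P{i:04d}" for i in range(params.n_samples)],
                "tissue": tissue,
                "os_time": time,
                "os_event": event,
            }
        )
    )
    truth = pd.Series([SUBTYPE_ORDER[s] for s in states], index=sample_ids, name="subtype")
    return expr, meta, truth


def simulate_paired_cohort(params: SimulationParams | None = None, seed: int = 42):
    """Simulate patient-paired normal/tumor samples.

    The normal state follows the normal prevalence; the tumor state is drawn
    from the transition-matrix row of the normal state. Returns
    ``(ExpressionMatrix, SampleTable, true_transitions)`` with
    ``true_transitions`` a DataFrame of patient_id, normal and tumor subtype.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    T = np.asarray(params.transition, dtype=float)
    signatures = _state_signatures(rng, params)
    normal_states = rng.choice(
        3, size=params.n_pairs, p=np.asarray(params.prevalence_normal, dtype=float)
    )
    tumor_states = np.array([rng.choice(3, p=T[s]) for s in normal_states])

    rows, profiles, ids = [], [], []
    for i, (ns, ts) in enumerate(zip(normal_states, tumor_states)):
        pid = f"P{i:04d}"
        for tissue, state in (("normal", ns), ("tumor", ts)):
            sid = f"{pid}_{tissue[0].upper()}"
            ids.append(sid)
            profiles.append(
                _expression_profile(rng, params, signatures, state, tissue == "tumor")
            )
            rows.append({"sample_id": sid, "patient_id": pid, "tissue": tissue})
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            np.column_stack(profiles), index=_gene_index(params), columns=ids
        ),
        normalized="log",
    )
    meta = SampleTable(data=pd.DataFrame(rows))
    truth = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(params.n_pairs)],
            "normal_subtype": [SUBTYPE_ORDER[s] for s in normal_states],
            "tumor_subtype": [SUBTYPE_ORDER[s] for s in tumor_states],
        }
    )
    return expr, meta, truth


def simulate_cell_counts(
    params: SimulationParams | None = None,
    seed: int = 42,
    n_tumor: int = 26,
    n_normal: int = 10,
):
    """Simulate annotated single-cell count tables per sample.

    Multinomial cell-type counts with tumor samples given a lower expected
    epithelial fraction; returns a DataFrame with one row per sample
    (columns: cell types + tissue). Default sample numbers echo a typical
    single-cell gastric atlas (26 tumor, 10 normal samples).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    rows = []
    for tissue, n in (("normal", n_normal), ("tumor", n_tumor)):
        props = params.cell_proportions[tissue]
        types = list(props)
        p = np.asarray([props[t] for t in types], dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"cell proportions for {tissue} must sum to 1")
        for i in range(n):
            counts = rng.multinomial(params.cells_per_sample, p)
            row = dict(zip(types, counts))
            row["sample_id"] = f"{tissue[0].upper()}C{i:03d}"
            row["tissue"] = tissue
            rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return df
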