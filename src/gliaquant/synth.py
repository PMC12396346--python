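"""Synthetic data generators with known ground truth.

Every downstream pipeline input can be generated here: a three-state
(OPC/OC/AC) count matrix with state-coupled marker genes, photometry traces
(exponential bleach + transient events + Gaussian noise), 3-D puncta fields
with a known colocalized fraction (optionally rendered as Gaussian-blob image
stacks), and Bernoulli-labelled per-cell marker tables.

All generators are deterministic given config + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .photometry import PhotometryTrace
from .puncta import ImageStack, PunctaSet
from .sc_state import STATE_KEYS, ExpressionMatrix

__all__ = [
    "ScSimConfig",
    "PhotoSimConfig",
    "PunctaSimConfig",
    "gen_expression",
    "gen_photometry",
    "event_integral",
    "gen_puncta",
    "render_puncta",
    "gen_puncta_stacks",
    "gen_cell_records",
]


# ---------------------------------------------------------------------------
# single-cell expression


@dataclass
class ScSimConfig:
    """Three-state single-cell count simulation.

    Signature genes of each state have their negative-binomial mean
    multiplied by ``exp(state_effect)`` in cells of that state; an optional
    "receptor" gene shares the shift of ``coupled_gene_state``. Cells are
    assigned to samples round-robin so every sample contains all states.
    """

    n_cells: int = 300
    n_genes: int = 2000
    n_samples: int = 3
    state_fractions: dict = field(
        default_factory=lambda: {"OPC": 1 / 3, "OC": 1 / 3, "AC": 1 / 3}
    )
    n_signature_genes_per_state: int = 50
    state_effect: float = 1.0
    library_size_mean: float = 5000.0
    noise_dispersion: float = 0.1
    coupled_gene_state: str | None = None
    platform: str = "umi"
    seed: int = 0

    def __post_init__(self):
        fr = self.state_fractions
        if set(fr) != set(STATE_KEYS):
            raise ValueError(f"state_fractions must have keys {STATE_KEYS}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")
        n_special = 3 * self.n_signature_genes_per_state + (
            1 if self.coupled_gene_state else 0
        )
        if n_special > self.n_genes:
            raise ValueError(
                "3 * n_signature_genes_per_state (+ receptor) must fit in n_genes"
            )
        if min(self.n_cells, self.n_genes, self.n_samples) <= 0:
            raise ValueError("n_cells, n_genes, n_samples must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be non-negative")
        if self.coupled_gene_state and self.coupled_gene_state not in STATE_KEYS:
            raise ValueError(f"coupled_gene_state must be one of {STATE_KEYS}")


RECEPTOR_GENE = "RECEPTOR0"


def gen_expression(config: ScSimConfig):
    """Simulate a count matrix; returns ``(matrix, true_state, signatures)``.

    ``true_state`` is the per-cell ground-truth state label and
    ``signatures`` maps OPC/OC/AC to their planted marker gene lists (the
    receptor gene, when present, is not part of any signature).
    """
    rng = np.random.default_rng(config.seed)
    nsig = config.n_signature_genes_per_state

    gene_ids, sig_idx = [], {}
    for st in STATE_KEYS:
        sig_idx[st] = list(range(len(gene_ids), len(gene_ids) + nsig))
        gene_ids.extend(f"{st}_SIG{j:04d}" for j in range(nsig))
    receptor_idx = None
    if config.coupled_gene_state:
        receptor_idx = len(gene_ids)
        gene_ids.append(RECEPTOR_GENE)
    gene_ids.extend(f"FILLER{j:05d}" for j in range(config.n_genes - len(gene_ids)))
    gene_ids = np.array(gene_ids, dtype=object)

    states = np.array(STATE_KEYS, dtype=object)
    probs = np.array([config.state_fractions[s] for s in STATE_KEYS])
    true_state = rng.choice(states, size=config.n_cells, p=probs)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base = base / base.sum() * config.library_size_mean  # expected library size

    mu = np.tile(base[:, None], (1, config.n_cells))
    boost = math.exp(config.state_effect)
    for st in STATE_KEYS:
        cells = np.flatnonzero(true_state == st)
        mu[np.ix_(sig_idx[st], cells)] *= boost
        if receptor_idx is not None and st == config.coupled_gene_state:
            mu[receptor_idx, cells] *= boost

    if config.noise_dispersion == 0:
        counts = rng.poisson(mu).astype(float)
    else:
        n = 1.0 / config.noise_dispersion
        counts = rng.negative_binomial(n, n / (n + mu)).astype(float)

    cell_ids = np.array([f"CELL{i:05d}" for i in range(config.n_cells)], dtype=object)
    sample_of_cell = np.array(
        [f"S{i % config.n_samples}" for i in range(config.n_cells)], dtype=object
    )
    matrix = ExpressionMatrix(
        values=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        sample_of_cell=sample_of_cell,
        platform_of_sample={
            f"S{j}": config.platform for j in range(config.n_samples)
        },
        malignant=np.ones(config.n_cells, dtype=bool),
        unit="counts",
    )
    signatures = {st: [gene_ids[i] for i in sig_idx[st]] for st in STATE_KEYS}
    return matrix, true_state, signatures


# ---------------------------------------------------------------------------
# photometry


@dataclass
class PhotoSimConfig:
    """Photometry trace = bleach curve + transient events + Gaussian noise.

    Events rise instantaneously at ``event_times`` and decay exponentially
    with ``event_tau``; this kernel has the closed-form window integral
    ``A * tau * (1 - exp(-T/tau))`` used as the ground-truth AUC.
    """

    duration: float = 300.0
    fs: float = 10.0
    bleach_model: str = "mono"
    bleach_params: dict = field(
        default_factory=lambda: {"A": 5.0, "tau": 60.0, "C": 1.0}
    )
    event_times: tuple = ()
    event_amplitude: float = 1.0
    event_tau: float = 2.0
    noise_sd: float = 0.05
    baseline_window: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.bleach_model not in ("mono", "bi"):
            raise ValueError("bleach_model must be 'mono' or 'bi'")
        taus = (
            [self.bleach_params["tau"]]
            if self.bleach_model == "mono"
            else [self.bleach_params["tau1"], self.bleach_params["tau2"]]
        )
        if any(tau <= 0 for tau in taus) or self.event_tau <= 0:
            raise ValueError("time constants must be positive")
        for te in self.event_times:
            if not (0 <= te <= self.duration):
                raise ValueError(f"event time {te} outside [0, {self.duration}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def event_integral(amplitude: float, tau: float, window_len: float) -> float:
    """Integral of ``A e^{-t/tau}`` over ``[0, T]``: A*tau*(1 - exp(-T/tau))."""
    return amplitude * tau * (1.0 - math.exp(-window_len / tau))


def gen_photometry(config: PhotoSimConfig):
    """Simulate a trace; returns ``(PhotometryTrace, ground_truth)``.

    Ground truth records the bleach model/parameters and, per event, its
    onset, amplitude, decay constant, and analytic integral to trace end.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration, 1.0 / config.fs)
    p = config.bleach_params
    if config.bleach_model == "mono":
        bleach = p["A"] * np.exp(-t / p["tau"]) + p["C"]
    else:
        bleach = (
            p["A1"] * np.exp(-t / p["tau1"])
            + p["A2"] * np.exp(-t / p["tau2"])
            + p["C"]
        )
    signal = bleach.copy()
    events = []
    for te in config.event_times:
        mask = t >= te
        signal[mask] += config.event_amplitude * np.exp(
            -(t[mask] - te) / config.event_tau
        )
        events.append(
            {
                "time": float(te),
                "amplitude": config.event_amplitude,
                "tau": config.event_tau,
                "auc_to_end": event_integral(
                    config.event_amplitude, config.event_tau, config.duration - te
                ),
            }
        )
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=len(t))

    baseline = config.baseline_window
    if baseline is None:
        b1 = min(config.event_times) if config.event_times else config.duration
        baseline = (0.0, min(b1, config.duration / 5.0))
    trace = PhotometryTrace(
        t=t, F=signal, fs=config.fs,
        baseline_window=baseline, stim_onsets=tuple(config.event_times),
    )
    truth = {
        "bleach_model": config.bleach_model,
        "bleach_params": dict(p),
        "events": events,
        "noise_sd": config.noise_sd,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# puncta fields


@dataclass
class PunctaSimConfig:
    """Two-channel 3-D puncta field with a known colocalized fraction.

    A ``colocalized_fraction`` of glioma (postsynaptic) puncta is placed at a
    uniformly chosen neuron (presynaptic) punctum plus isotropic Gaussian
    displacement of sd ``coloc_distance_sd``; the remainder is uniform.
    ``margin`` shrinks the uniform placement region away from the borders and
    ``min_separation`` enforces a minimum spacing within each channel.
    """

    volume: tuple = (20.0, 20.0, 6.0)  # (x, y, z) um
    n_neuron_puncta: int = 100
    n_glioma_puncta: int = 100
    colocalized_fraction: float = 0.5
    coloc_distance_sd: float = 0.2
    voxel_size: tuple = (0.15, 0.1, 0.1)  # (dz, dy, dx) um
    blob_sigma: float = 0.25
    peak_snr: float = 10.0
    margin: float = 0.0
    min_separation: float = 0.0
    background: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if len(self.volume) != 3 or min(self.volume) <= 0:
            raise ValueError("volume must be three positive extents (x, y, z)")
        if not (0.0 <= self.colocalized_fraction <= 1.0):
            raise ValueError("colocalized_fraction must be in [0, 1]")
        if min(self.volume) < 4 * self.blob_sigma:
            raise ValueError("extents must be at least 4 * blob_sigma")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.coloc_distance_sd < 0 or self.min_separation < 0 or self.margin < 0:
            raise ValueError("distances must be non-negative")


def _uniform_points(rng, n, volume, margin, min_sep):
    lo = np.full(3, margin)
    hi = np.asarray(volume) - margin
    if np.any(hi <= lo):
        raise ValueError("margin leaves no placement volume")
    if min_sep <= 0:
        return rng.uniform(lo, hi, size=(n, 3))
    pts = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 10000 * max(n, 1):
            raise RuntimeError("could not place points at requested min_separation")
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - q) >= min_sep for q in pts):
            pts.append(cand)
    return np.array(pts)


def gen_puncta(config: PunctaSimConfig):
    """Simulate point sets; returns ``(pre_set, post_set, coloc_truth)``.

    ``coloc_truth`` is a boolean array flagging, for each postsynaptic
    (glioma) punctum, whether it was planted at a presynaptic punctum.
    """
    rng = np.random.default_rng(config.seed)
    neuron = _uniform_points(
        rng, config.n_neuron_puncta, config.volume, config.margin,
        config.min_separation,
    )
    n_coloc = int(round(config.colocalized_fraction * config.n_glioma_puncta))
    n_free = config.n_glioma_puncta - n_coloc
    parts = []
    if n_coloc:
        anchors = neuron[rng.integers(0, len(neuron), size=n_coloc)]
        placed = anchors + rng.normal(0.0, config.coloc_distance_sd, size=(n_coloc, 3))
        placed = np.clip(placed, 0.0, np.asarray(config.volume))
        parts.append(placed)
    if n_free:
        parts.append(
            _uniform_points(rng, n_free, config.volume, config.margin,
                            config.min_separation)
        )
    glioma = np.vstack(parts) if parts else np.empty((0, 3))
    truth = np.zeros(config.n_glioma_puncta, dtype=bool)
    truth[:n_coloc] = True
    pre = PunctaSet(channel="presynaptic", coords=neuron)
    post = PunctaSet(channel="postsynaptic", coords=glioma)
    return pre, post, truth


def render_puncta(points: np.ndarray, config: PunctaSimConfig, rng=None) -> ImageStack:
    """Render (x, y, z) um points as Gaussian blobs over a flat background.

    Blob peaks are ``peak_snr`` times the Gaussian noise sd (fixed at 1);
    points snap to the nearest voxel centre before blurring.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dz, dy, dx = config.voxel_size
    vx, vy, vz = config.volume
    shape = (
        max(int(round(vz / dz)), 1),
        max(int(round(vy / dy)), 1),
        max(int(round(vx / dx)), 1),
    )
    sigma_px = np.array([config.blob_sigma / dz, config.blob_sigma / dy,
                         config.blob_sigma / dx])
    noise_sd = 1.0
    peak = config.peak_snr * noise_sd
    # a unit impulse blurred with sigma has peak 1/((2*pi)^{3/2} prod(sigma))
    mass = peak * (2 * math.pi) ** 1.5 * sigma_px.prod()
    img = np.zeros(shape)
    for x, y, z in np.asarray(points).reshape(-1, 3):
        iz = min(max(int(round(z / dz)), 0), shape[0] - 1)
        iy = min(max(int(round(y / dy)), 0), shape[1] - 1)
        ix = min(max(int(round(x / dx)), 0), shape[2] - 1)
        img[iz, iy, ix] += mass
    img = ndimage.gaussian_filter(img, sigma=sigma_px)
    img += config.background
    img += rng.normal(0.0, noise_sd, size=shape)
    return ImageStack(data=np.clip(img, 0.0, None), voxel_size=config.voxel_size)


def gen_puncta_stacks(config: PunctaSimConfig):
    """Point sets plus rendered two-channel stacks.

    Returns ``(stack_pre, stack_post, pre_set, post_set, coloc_truth)``; both
    stacks share one noise stream seeded from the config.
    """
    pre, post, truth = gen_puncta(config)
    rng = np.random.default_rng([config.seed, 1])
    stack_pre = render_puncta(pre.coords, config, rng=rng)
    stack_pre.channel = "presynaptic"
    stack_post = render_puncta(post.coords, config, rng=rng)
    stack_post.channel = "postsynaptic"
    return stack_pre, stack_post, pre, post, truth


# ---------------------------------------------------------------------------
# cell records


def gen_cell_records(
    n_fields: int,
    cells_per_field: int,
    p_edu: float,
    seed: int = 0,
    group_id: str = "G1",
) -> pd.DataFrame:
    """Per-cell marker table with EdU drawn Bernoulli(p_edu).

    All cells are positive for the denominator markers (DAPI, HNA, GFP) and
    for the identity markers (Pdgfra, Olig2, H3K27M).
    """
    if not (0.0 <= p_edu <= 1.0):
        raise ValueError(f"p_edu must be in [0, 1], got {p_edu}")
    if n_fields <= 0 or cells_per_field <= 0:
        raise ValueError("n_fields and cells_per_field must be positive")
    rng = np.random.default_rng(seed)
    n = n_fields * cells_per_field
    edu = rng.random(n) < p_edu
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "field_id": np.repeat([f"F{j}" for j in range(n_fields)], cells_per_field),
            "group_id": group_id,
            "EdU": edu,
            "DAPI": True,
            "HNA": True,
            "GFP": True,
            "Pdgfra": True,
            "Olig2": True,
            "H3K27M": True,
        }
    )
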