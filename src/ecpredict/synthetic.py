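"""Synthetic resting-state dataset generator.

Produces everything the downstream pipeline consumes without any external
data: integer questionnaire scores from a moment-matched truncated normal, a
seven-network parcel atlas, stable ground-truth effective-connectivity (EC)
matrices, per-subject EC variation linearly linked to the behavioural score
on a chosen set of within-network edges, and forward-simulated BOLD time
series (linear latent dynamics -> haemodynamic convolution -> TR sampling ->
measurement noise -> band-pass filter -> z-scoring).

The defaults emulate the structure of a resting-state childhood-trauma
cohort: 206 subjects, 100 cortical parcels, TR = 2 s, 230 retained volumes,
signal content restricted to 0.01-0.1 Hz, and CTQ total scores with mean
34.7, SD 7.8 on the truncated range 25-61.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .atlas import NETWORK_LABELS, NetworkAtlas
from .datatypes import ParcelTimeSeries, as_weights
from .errors import ConfigError, StabilityError

__all__ = [
    "SimulationConfig",
    "GroundTruthModel",
    "DEFAULT_NETWORK_SIZES",
    "make_phenotypes",
    "make_atlas",
    "make_ground_truth_ec",
    "make_subject_ecs",
    "simulate_bold",
    "planted_network_model",
    "canonical_hrf",
]

#: Approximate per-network parcel counts of a 100-parcel seven-network
#: cortical parcellation (proportions, not exact published counts).
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "Vis": 17,
    "SMN": 16,
    "DAN": 13,
    "VAN": 12,
    "Lim": 10,
    "FPN": 13,
    "DMN": 19,
}

#: Duration (s) of the canonical haemodynamic response kernel.
HRF_DURATION = 32.0


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-simulation settings.

    ``innovation_sd`` drives the latent neural dynamics (per sqrt-second);
    ``measurement_noise_sd`` is observation noise added to the unit-variance
    BOLD signal before filtering, so 0.3 corresponds to a signal-to-noise
    ratio of about 3.3.
    """

    n_subjects: int = 206
    n_regions: int = 100
    tr: float = 2.0
    n_volumes: int = 230
    integration_step: float = 0.1
    innovation_sd: float = 1.0
    measurement_noise_sd: float = 0.3
    band: tuple[float, float] = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_regions <= 0 or self.n_volumes <= 0:
            raise ConfigError("counts must be positive")
        if not 0 < self.integration_step < self.tr:
            raise ConfigError("integration_step must lie in (0, tr)")
        nyquist = 0.5 / self.tr
        low, high = self.band
        if not 0 <= low < high < nyquist:
            raise ConfigError(f"band must satisfy 0 <= low < high < Nyquist ({nyquist} Hz)")
        if self.innovation_sd <= 0 or self.measurement_noise_sd < 0:
            raise ConfigError("noise SDs must be positive (measurement SD may be 0)")


@dataclass(frozen=True)
class GroundTruthModel:
    """Ground truth for a planted EC-score association.

    ``effect_edges`` are (target, source) parcel pairs whose weight varies
    linearly with the standardized behavioural score at slope
    ``effect_sizes`` (1/s per score SD); every other off-diagonal edge only
    receives between-subject Gaussian jitter of SD ``edge_noise_sd``.
    """

    base_ec: np.ndarray
    effect_edges: tuple[tuple[int, int], ...]
    effect_sizes: np.ndarray
    edge_noise_sd: float
    atlas: NetworkAtlas
    seed: int = 0

    def __post_init__(self) -> None:
        base = np.asarray(self.base_ec, dtype=float)
        object.__setattr__(self, "base_ec", base)
        object.__setattr__(self, "effect_sizes", np.asarray(self.effect_sizes, dtype=float))
        if len(self.effect_edges) != self.effect_sizes.size:
            raise ConfigError("effect_edges and effect_sizes lengths differ")
        if not np.all(np.isfinite(self.effect_sizes)):
            raise ConfigError("effect sizes must be finite")
        if _spectral_abscissa(base) >= 0:
            raise StabilityError("base EC is not stable (spectral abscissa >= 0)")
        labels = np.asarray(self.atlas.labels, dtype=object)
        for t, s in self.effect_edges:
            if not (0 <= t < base.shape[0] and 0 <= s < base.shape[0]):
                raise ConfigError(f"effect edge ({t}, {s}) out of range")
            if labels[t] != labels[s]:
                raise ConfigError(
                    f"effect edge ({t}, {s}) crosses networks "
                    f"({labels[t]} -> {labels[s]}); edges must stay within one block"
                )
        if self.edge_noise_sd < 0:
            raise ConfigError("edge_noise_sd must be non-negative")


def _spectral_abscissa(a: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(a).real))


def _truncnorm_params(mean: float, sd: float, low: float, high: float):
    """Underlying (loc, scale) so that the *truncated* law has the target moments.

    The reported sample mean/SD describe the truncated distribution itself, so
    the generating normal must be adjusted: solve the two moment equations
    numerically.
    """

    def moments(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (low - loc) / scale, (high - loc) / scale
        d = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - solver is robust for sane inputs
        raise ConfigError(f"could not match truncated-normal moments: {sol.message}")
    loc, log_scale = sol.x
    return float(loc), float(np.exp(log_scale))


def make_phenotypes(
    n_subjects: int = 206,
    mean: float = 34.7,
    sd: float = 7.8,
    bounds: tuple[float, float] = (25, 61),
    seed: int = 0,
) -> pd.DataFrame:
    """Integer questionnaire totals from a moment-matched truncated normal.

    Returns a table with columns ``subject_id`` and ``ctq_total``; every score
    lies in ``bounds`` and the population mean/SD of the truncated law match
    the targets (before integer rounding, whose effect is negligible here).
    """
    if n_subjects <= 0:
        raise ConfigError("n_subjects must be positive")
    if sd <= 0:
        raise ConfigError("sd must be positive")
    low, high = bounds
    if low > high:
        raise ConfigError("bounds must satisfy low <= high")
    rng = np.random.default_rng(seed)
    if low == high:
        scores = np.full(n_subjects, low)
    else:
        loc, scale = _truncnorm_params(mean, sd, low, high)
        a, b = (low - loc) / scale, (high - loc) / scale
        draws = stats.truncnorm(a, b, loc=loc, scale=scale).rvs(n_subjects, random_state=rng)
        scores = np.clip(np.rint(draws), low, high)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
            "ctq_total": scores.astype(int),
        }
    )


def make_atlas(network_sizes: dict[str, int] | None = None) -> NetworkAtlas:
    """Atlas with contiguous parcel blocks, one per canonical network.

    ``network_sizes`` must contain exactly the seven canonical labels with
    positive counts; block order follows the canonical label order.
    """
    sizes = dict(DEFAULT_NETWORK_SIZES if network_sizes is None else network_sizes)
    if set(sizes) != set(NETWORK_LABELS):
        missing = set(NETWORK_LABELS) - set(sizes)
        extra = set(sizes) - set(NETWORK_LABELS)
        raise ConfigError(f"network_sizes must have exactly the seven labels; missing={sorted(missing)} extra={sorted(extra)}")
    labels: list[str] = []
    for net in NETWORK_LABELS:
        count = int(sizes[net])
        if count <= 0:
            raise ConfigError(f"network {net} has non-positive size {count}")
        labels.extend([net] * count)
    return NetworkAtlas(labels=tuple(labels))


def make_ground_truth_ec(
    atlas: NetworkAtlas,
    self_strength: float = -0.5,
    off_diag_density: float = 0.15,
    off_diag_sd: float = 0.2,
    seed: int = 0,
    max_rescale: int = 100,
) -> np.ndarray:
    """Stable random EC matrix over the atlas parcels.

    Self-connections are fixed at ``self_strength`` (must be negative); each
    off-diagonal entry is nonzero with probability ``off_diag_density`` and
    then Gaussian with SD ``off_diag_sd``.  If the resulting system is
    unstable, off-diagonal weights are shrunk by 10% repeatedly until every
    eigenvalue has a strictly negative real part.
    """
    if self_strength >= 0:
        raise ConfigError("self_strength must be negative")
    if not 0 <= off_diag_density <= 1:
        raise ConfigError("off_diag_density must be in [0, 1]")
    n = atlas.n_parcels
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < off_diag_density
    np.fill_diagonal(mask, False)
    off = np.where(mask, rng.normal(0.0, off_diag_sd, (n, n)), 0.0)
    ec = off + np.diag(np.full(n, float(self_strength)))
    for _ in range(max_rescale):
        if _spectral_abscissa(ec) < 0:
            return ec
        off *= 0.9
        ec = off + np.diag(np.full(n, float(self_strength)))
    raise StabilityError("could not stabilise ground-truth EC within iteration cap")


def _stabilise_subject(ec: np.ndarray, max_rescale: int = 50) -> np.ndarray:
    """Shrink off-diagonal weights until stable; raise if the cap is hit."""
    diag = np.diag(np.diag(ec))
    off = ec - diag
    for _ in range(max_rescale):
        cand = off + diag
        if _spectral_abscissa(cand) < 0:
            return cand
        off *= 0.9
    raise StabilityError("subject EC could not be stabilised")


def make_subject_ecs(model: GroundTruthModel, phenotypes: pd.DataFrame) -> list[np.ndarray]:
    """Per-subject EC matrices with the planted linear score link.

    For subject ``s`` with standardized score ``z_s``, each effect edge ``e``
    takes ``base + slope_e * z_s + jitter`` and every other off-diagonal edge
    ``base + jitter``; self-connections are left at their base value.  Every
    matrix is re-checked (and if necessary re-shrunk) for stability.
    """
    scores = phenotypes["ctq_total"].to_numpy(dtype=float)
    sd = scores.std()
    z = np.zeros_like(scores) if sd == 0 else (scores - scores.mean()) / sd
    rng = np.random.default_rng(model.seed)
    n = model.base_ec.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    edges = np.asarray(model.effect_edges, dtype=int)
    out: list[np.ndarray] = []
    for z_s in z:
        ec = model.base_ec.copy()
        if model.edge_noise_sd > 0:
            jitter = rng.normal(0.0, model.edge_noise_sd, (n, n))
            ec[off_mask] += jitter[off_mask]
        if edges.size:
            ec[edges[:, 0], edges[:, 1]] += model.effect_sizes * z_s
        out.append(_stabilise_subject(ec))
    return out


def canonical_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Canonical double-gamma haemodynamic response (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), sampled at ``dt`` and normalised to unit peak."""
    t = np.arange(0.0, duration, dt)
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.max()


def simulate_bold(ec, cfg: SimulationConfig) -> ParcelTimeSeries:
    """Forward-simulate band-limited, z-scored BOLD from linear dynamics.

    Integrates ``dx/dt = A x + w`` (Gaussian innovations ``w``) with Euler
    steps, convolves each region with the canonical haemodynamic response,
    samples at the TR, adds measurement noise, applies an ideal (rectangular
    frequency-domain) band-pass filter and z-scores each region.
    """
    a = as_weights(ec)
    if a.shape[0] != cfg.n_regions:
        cfg = dataclasses.replace(cfg, n_regions=a.shape[0])
    if _spectral_abscissa(a) >= 0:
        raise StabilityError("EC matrix is unstable; cannot simulate")
    if cfg.n_volumes * cfg.tr < HRF_DURATION:
        raise ConfigError(
            f"run duration {cfg.n_volumes * cfg.tr:.0f} s shorter than the "
            f"{HRF_DURATION:.0f} s haemodynamic response"
        )
    rng = np.random.default_rng(cfg.seed)
    h = cfg.integration_step
    burn = HRF_DURATION  # settle latent dynamics and fill the HRF history
    n_steps = int(round((burn + cfg.n_volumes * cfg.tr) / h))
    n = a.shape[0]

    x = np.zeros((n, n_steps))
    innov = rng.normal(0.0, cfg.innovation_sd * np.sqrt(h), (n, n_steps))
    step = np.eye(n) + h * a
    for k in range(1, n_steps):
        x[:, k] = step @ x[:, k - 1] + innov[:, k]

    hrf = canonical_hrf(h)
    bold = signal.fftconvolve(x, hrf[None, :], mode="full", axes=1)[:, :n_steps] * h

    stride = int(round(cfg.tr / h))
    start = int(round(burn / h))
    idx = start + stride * np.arange(cfg.n_volumes)
    y = bold[:, idx]

    # normalise to unit variance so measurement_noise_sd sets the SNR directly
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    y = y / sd
    if cfg.measurement_noise_sd > 0:
        y = y + rng.normal(0.0, cfg.measurement_noise_sd, y.shape)

    # ideal band-pass: zero every DFT bin outside [low, high]
    freqs = np.fft.rfftfreq(cfg.n_volumes, cfg.tr)
    spec = np.fft.rfft(y, axis=1)
    keep = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    spec[:, ~keep] = 0.0
    y = np.fft.irfft(spec, n=cfg.n_volumes, axis=1)

    sd = y.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise StabilityError("filtered signal is constant in at least one region")
    y = (y - y.mean(axis=1, keepdims=True)) / sd
    return ParcelTimeSeries(data=y, tr=cfg.tr)


def planted_network_model(
    atlas: NetworkAtlas,
    network: str = "DMN",
    n_effect_edges: int = 12,
    effect_size: float = 0.06,
    edge_noise_sd: float = 0.09,
    base_ec: np.ndarray | None = None,
    seed: int = 0,
) -> GroundTruthModel:
    """Ground-truth model with the score effect planted on within-network edges.

    Randomly picks ``n_effect_edges`` directed off-diagonal edges inside the
    given network block; slopes alternate in sign (half the edges strengthen
    with the score, half weaken), so both tails of the feature-score
    correlation distribution carry signal, as the per-direction feature
    selector assumes.  The defaults give a per-edge weight-score correlation
    magnitude of ``|slope| / sqrt(slope**2 + edge_noise_sd**2)`` at the
    ground-truth level.
    """
    rng = np.random.default_rng(seed)
    if base_ec is None:
        base_ec = make_ground_truth_ec(atlas, seed=seed)
    idx = atlas.parcels_in(network)
    pairs = [(int(t), int(s)) for t in idx for s in idx if t != s]
    if n_effect_edges > len(pairs):
        raise ConfigError(
            f"requested {n_effect_edges} effect edges but network {network!r} "
            f"has only {len(pairs)} directed off-diagonal edges"
        )
    chosen = rng.choice(len(pairs), size=n_effect_edges, replace=False)
    edges = tuple(pairs[int(i)] for i in chosen)
    signs = np.where(np.arange(n_effect_edges) % 2 == 0, 1.0, -1.0)
    return GroundTruthModel(
        base_ec=base_ec,
        effect_edges=edges,
        effect_sizes=signs * effect_size,
        edge_noise_sd=edge_noise_sd,
        atlas=atlas,
        seed=seed + 1,
    )
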