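"""Synthetic-data generators with known ground truth.

Every input class the analysis pipeline consumes can be generated here:
single-fluorophore and oligomer intensity datasets (for subunit counting),
Gaussian-PSF spot images (for detection), per-complex event timelines (for
nucleation/binding/release scoring), and two-state dynamic-instability
tracks (for growth-rate and catastrophe statistics).  Generators emulate
the statistical structure of single-molecule TIRF data — right-skewed
single-fluorophore brightness, binomial fluorophore maturation, Gaussian
point-spread functions with read (and optionally shot) noise, Bernoulli
per-window event processes and exponential catastrophe waiting times —
so that each downstream estimator can be validated by parameter recovery.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonomerModel",
    "OligomerScenario",
    "EventProcessParams",
    "DynamicsParams",
    "IntensityDataset",
    "EventTable",
    "Track",
    "gen_monomer_intensities",
    "gen_oligomer_dataset",
    "render_spot_image",
    "gen_event_table",
    "gen_dynamics_tracks",
    "scenario_bimodal_gcp3",
    "write_image_tiff",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomerModel:
    """Single-fluorophore intensity distribution.

    Parameters
    ----------
    family : {"lognormal", "gamma", "delta"}
        Distribution family.  The measured brightness of a single GFP on a
        camera is right-skewed and nonnegative; lognormal is the default.
        ``delta`` (all mass at ``mean``) is a degenerate model used in
        exactness tests.
    mean : float
        Mean intensity in arbitrary units (a.u.); must be positive.
    cv : float
        Coefficient of variation (s.d./mean).  Ignored for ``delta``.
    background_sd : float
        S.d. of additive zero-mean Gaussian background noise applied per
        punctum (a.u.); default 0.
    """

    family: str = "lognormal"
    mean: float = 1000.0
    cv: float = 0.35
    background_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "delta"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.family != "delta" and self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be nonnegative")

    @property
    def var(self) -> float:
        """Closed-form variance of a single draw (excluding background)."""
        if self.family == "delta":
            return 0.0
        return (self.cv * self.mean) ** 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be nonnegative")
        if self.family == "delta":
            return np.full(n, self.mean)
        if self.family == "lognormal":
            sigma2 = np.log1p(self.cv ** 2)
            mu = np.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
        # gamma: shape k = 1/cv^2, scale = mean*cv^2
        k = 1.0 / self.cv ** 2
        return rng.gamma(shape=k, scale=self.mean / k, size=n)


@dataclass(frozen=True)
class OligomerScenario:
    """Population of N-mer puncta with incomplete fluorophore maturation.

    ``weights`` maps oligomer size N (>=1) to its probability; ``p_active``
    is the probability that an individual fluorophore is fluorescent
    (folding/maturation/pre-bleaching proxy).  Puncta in which zero
    fluorophores are active are undetectable and are resampled (the count
    of resamples is reported on the generated dataset).
    """

    weights: Mapping[int, float]
    p_active: float = 1.0
    n_puncta: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if not w:
            raise ValueError("weights must be non-empty")
        if any(int(k) != k or k < 1 for k in w):
            raise ValueError("oligomer sizes must be integers >= 1")
        vals = np.asarray(list(w.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {vals.sum()!r})")
        if not 0.0 <= self.p_active <= 1.0:
            raise ValueError("p_active must be in [0, 1]")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be nonnegative")


def scenario_bimodal_gcp3(n_puncta: int = 20_000, seed: int = 0,
                          p_active: float = 1.0) -> OligomerScenario:
    """Bimodal GCP3-tagged population preset.

    37% of the mass on 1–2 fluorophores (small complexes carrying a single
    tagged subunit) and 36% on 4–5 (complete rings with five tagged
    subunits), the remainder on intermediate/larger species.
    """
    weights = {1: 0.185, 2: 0.185, 3: 0.14, 4: 0.18, 5: 0.18, 6: 0.13}
    return OligomerScenario(weights=weights, p_active=p_active,
                            n_puncta=n_puncta, seed=seed)


@dataclass(frozen=True)
class EventProcessParams:
    """Bernoulli-per-window event process for surface-immobilized complexes.

    Each complex independently nucleates a microtubule within the
    observation window with probability ``p_nucleate_per_window``; active
    complexes recruit a minus-end binder with probability
    ``p_bind_given_active``; bound minus ends start growing (and the
    microtubule is released) with probability ``p_release_given_bound``
    after a delay drawn from ``delay_law``.  Independently, active
    complexes may lose their microtubule to depolymerization
    (``p_depoly_given_active``) and subsequently re-nucleate
    (``p_renucleate_given_depoly``).
    """

    n_complexes: int = 1000
    p_nucleate_per_window: float = 0.03
    p_bind_given_active: float = 0.3
    p_release_given_bound: float = 0.5
    p_depoly_given_active: float = 0.2
    p_renucleate_given_depoly: float = 0.5
    delay_law: tuple[str, float, float] = ("uniform", 50.0, 350.0)
    window_s: float = 600.0
    n_fov: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_nucleate_per_window", "p_bind_given_active",
                     "p_release_given_bound", "p_depoly_given_active",
                     "p_renucleate_given_depoly"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.n_complexes < 0:
            raise ValueError("n_complexes must be nonnegative")
        if self.n_fov < 1:
            raise ValueError("n_fov must be >= 1")
        kind = self.delay_law[0]
        if kind not in ("uniform", "constant", "exponential"):
            raise ValueError(f"unknown delay law {kind!r}")


@dataclass(frozen=True)
class DynamicsParams:
    """Two-state (growth/shrinkage) dynamic-instability track generator.

    Velocities are in µm/min, switching rates (catastrophe ``f_cat``,
    rescue ``f_res``) in events/s, sampling interval ``dt`` and duration
    ``t_max`` in seconds.  Position noise is additive Gaussian (µm).
    """

    v_growth: float = 2.0
    v_shrink: float = 15.0
    f_cat: float = 0.004
    f_res: float = 0.02
    dt: float = 3.0
    t_max: float = 1800.0
    n_tracks: int = 10
    position_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_growth <= 0 or self.v_shrink <= 0:
            raise ValueError("velocities must be positive")
        if self.f_cat < 0 or self.f_res < 0:
            raise ValueError("rates must be nonnegative")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be nonnegative")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityDataset:
    """Per-punctum background-corrected integrated intensities.

    ``true_size`` holds the ground-truth oligomer size when generated
    synthetically (absent for measured data); ``n_resampled`` counts
    undetectable (zero active fluorophores) puncta that were redrawn.
    """

    intensities: np.ndarray
    true_sizes: np.ndarray | None = None
    label: str = ""
    n_resampled: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.true_sizes is not None:
            self.true_sizes = np.asarray(self.true_sizes, dtype=int)
            if self.true_sizes.shape != self.intensities.shape:
                raise ValueError("true_sizes must match intensities in shape")

    def __len__(self) -> int:
        return self.intensities.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"intensity": self.intensities})
        if self.true_sizes is not None:
            df["true_size"] = self.true_sizes
        df["label"] = self.label
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps(
            {"label": self.label, "n_resampled": self.n_resampled,
             **self.meta}, indent=2, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensityDataset":
        df = pd.read_csv(path)
        sizes = df["true_size"].to_numpy() if "true_size" in df else None
        label = str(df["label"].iloc[0]) if "label" in df and len(df) else ""
        return cls(df["intensity"].to_numpy(), sizes, label=label)


EVENT_COLUMNS = ["complex_id", "fov", "active", "t_nucleate", "t_depoly",
                 "t_renucleate", "t_bind", "t_growth_onset", "t_release"]


@dataclass
class EventTable:
    """Per-complex event timeline within an observation window.

    ``data`` columns: complex_id, fov, active (bool), and the event times
    t_nucleate, t_depoly, t_renucleate, t_bind, t_growth_onset, t_release
    in seconds (NaN where the event did not occur).  Present times obey
    t_nucleate <= t_bind <= t_growth_onset <= t_release and fall inside
    ``window``.
    """

    data: pd.DataFrame
    window: tuple[float, float] = (0.0, 600.0)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        t0, t1 = self.window
        if not t1 > t0:
            raise ValueError("window must have positive duration")
        self.validate()

    def validate(self) -> None:
        d = self.data
        t0, t1 = self.window
        chain = ["t_nucleate", "t_bind", "t_growth_onset", "t_release"]
        for a, b in zip(chain, chain[1:]):
            both = d[a].notna() & d[b].notna()
            if (d.loc[both, a] > d.loc[both, b] + 1e-9).any():
                raise ValueError(f"event ordering violated: {a} > {b}")
        for c in chain + ["t_depoly", "t_renucleate"]:
            vals = d[c].dropna()
            if ((vals < t0 - 1e-9) | (vals > t1 + 1e-9)).any():
                raise ValueError(f"{c} outside observation window")

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps(
            {"window": list(self.window), **self.ground_truth},
            indent=2, default=float))

    @classmethod
    def from_csv(cls, path: str | Path,
                 window: tuple[float, float] = (0.0, 600.0)) -> "EventTable":
        return cls(pd.read_csv(path), window=window)


@dataclass
class Track:
    """Time series of a microtubule end position.

    ``times`` in seconds (uniformly spaced at ``frame_interval``),
    ``positions`` in µm.  ``true_phases`` carries the generator's
    per-sample state ('growth'/'shrink') when synthetic.
    """

    times: np.ndarray
    positions: np.ndarray
    frame_interval: float
    true_phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")
        if self.times.size >= 2:
            dts = np.diff(self.times)
            if (dts <= 0).any():
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dts - self.frame_interval)) > 1e-9:
                raise ValueError("times must be uniformly spaced at "
                                 "frame_interval")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.times, "position_um": self.positions}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Track":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy()
        dt = float(t[1] - t[0]) if t.size >= 2 else 1.0
        return cls(t, df["position_um"].to_numpy(), frame_interval=dt)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_monomer_intensities(model: MonomerModel, n: int,
                            seed: int = 0) -> IntensityDataset:
    """Sample ``n`` single-fluorophore punctum intensities."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    x = model.sample(n, rng)
    if model.background_sd > 0:
        x = x + rng.normal(0.0, model.background_sd, size=n)
    return IntensityDataset(x, np.ones(n, dtype=int), label="monomer",
                            meta={"model": model.family, "mean": model.mean,
                                  "cv": model.cv})


def gen_oligomer_dataset(scenario: OligomerScenario,
                         model: MonomerModel) -> IntensityDataset:
    """Sample a population of N-mer puncta.

    Each punctum draws its size N from ``scenario.weights``, its active
    fluorophore count k ~ Binomial(N, p_active) conditioned on k >= 1
    (zero-active puncta are invisible and are resampled; the resample
    count is recorded), and its intensity as the sum of k independent
    monomer draws plus Gaussian background noise.
    """
    rng = np.random.default_rng(scenario.seed)
    sizes_avail = np.array(sorted(scenario.weights), dtype=int)
    probs = np.array([scenario.weights[int(s)] for s in sizes_avail])
    probs = probs / probs.sum()

    n = scenario.n_puncta
    sizes = np.empty(n, dtype=int)
    actives = np.empty(n, dtype=int)
    n_resampled = 0
    filled = 0
    while filled < n:
        m = n - filled
        N = rng.choice(sizes_avail, size=m, p=probs)
        k = rng.binomial(N, scenario.p_active)
        keep = k >= 1
        n_resampled += int((~keep).sum())
        kept = int(keep.sum())
        sizes[filled:filled + kept] = N[keep]
        actives[filled:filled + kept] = k[keep]
        filled += kept
        if scenario.p_active == 0.0:
            raise ValueError("p_active = 0 makes every punctum undetectable")

    total_active = int(actives.sum())
    draws = model.sample(total_active, rng)
    # sum k_i consecutive draws per punctum
    stops = np.cumsum(actives)
    starts = stops - actives
    csum = np.concatenate([[0.0], np.cumsum(draws)])
    intensities = csum[stops] - csum[starts]
    if model.background_sd > 0:
        intensities = intensities + rng.normal(0.0, model.background_sd, n)
    return IntensityDataset(
        intensities, sizes, label="oligomer", n_resampled=n_resampled,
        meta={"weights": {int(k): float(v)
                          for k, v in scenario.weights.items()},
              "p_active": scenario.p_active, "active_counts_mean":
              float(actives.mean()) if n else float("nan")})


def render_spot_image(spots: Sequence[tuple[float, float, float]],
                      psf_sigma: float, background: float, noise_sd: float,
                      shape: tuple[int, int], seed: int = 0,
                      poisson: bool = False) -> np.ndarray:
    """Render isotropic Gaussian-PSF spots onto a noisy background.

    ``spots`` is a list of (x, y, amplitude) with 0-based pixel-centre
    coordinates (x = column, y = row).  The noiseless image is
    background + sum of A·exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2)); Gaussian
    read noise of s.d. ``noise_sd`` is added, and with ``poisson=True``
    the noiseless image is first replaced by a Poisson draw (shot noise).
    Returns a float64 image.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    H, W = shape
    img = np.full((H, W), float(background))
    yy, xx = np.mgrid[0:H, 0:W]
    for x0, y0, amp in spots:
        if not (0 <= x0 < W and 0 <= y0 < H):
            raise ValueError(f"spot ({x0}, {y0}) outside image bounds")
        img += amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                            / (2.0 * psf_sigma ** 2))
    rng = np.random.default_rng(seed)
    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write an image (or stack) as 16-bit unsigned grayscale TIFF."""
    import tifffile

    arr = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def _sample_delay(law: tuple[str, float, float], size: int,
                  rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "constant":
        return np.full(size, float(law[1]))
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    return rng.exponential(law[1], size=size)  # exponential: law[1] = mean


def gen_event_table(params: EventProcessParams) -> EventTable:
    """Generate a per-complex event timeline table.

    Event times are placed early in the window so that downstream events
    (binding delay up to 350 s by default) remain observable: nucleation
    in the first tenth of the window, binding within a further tenth.
    Complexes that never nucleate are inactive rows with all times NaN.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_complexes
    w = params.window_s
    nuc = rng.random(n) < params.p_nucleate_per_window
    t_nuc = np.where(nuc, rng.uniform(0, 0.1 * w, n), np.nan)

    bind = nuc & (rng.random(n) < params.p_bind_given_active)
    t_bind = np.where(bind, t_nuc + rng.uniform(0, 0.1 * w, n), np.nan)

    rel = bind & (rng.random(n) < params.p_release_given_bound)
    delays = _sample_delay(params.delay_law, n, rng)
    t_growth = np.where(rel, t_bind + delays, np.nan)
    # censor growth onsets falling beyond the window
    censored = rel & (t_growth > w)
    t_growth = np.where(censored, np.nan, t_growth)
    t_release = t_growth.copy()

    depoly = nuc & (rng.random(n) < params.p_depoly_given_active)
    t_dep = np.where(depoly, t_nuc + rng.uniform(0, 0.25 * w, n), np.nan)
    renuc = depoly & (rng.random(n) < params.p_renucleate_given_depoly)
    t_renuc = np.where(renuc, t_dep + rng.uniform(0, 0.125 * w, n), np.nan)

    fov = np.arange(n) % params.n_fov
    df = pd.DataFrame({
        "complex_id": np.arange(n), "fov": fov, "active": nuc,
        "t_nucleate": t_nuc, "t_depoly": t_dep, "t_renucleate": t_renuc,
        "t_bind": t_bind, "t_growth_onset": t_growth,
        "t_release": t_release})
    truth = {
        "p_nucleate_per_window": params.p_nucleate_per_window,
        "p_bind_given_active": params.p_bind_given_active,
        "p_release_given_bound": params.p_release_given_bound,
        "p_depoly_given_active": params.p_depoly_given_active,
        "p_renucleate_given_depoly": params.p_renucleate_given_depoly,
        "n_censored_growth_onsets": int(censored.sum())}
    return EventTable(df, window=(0.0, w), ground_truth=truth)


def gen_dynamics_tracks(params: DynamicsParams) -> list[Track]:
    """Generate two-state telegraph-process end-position tracks.

    The end grows at ``v_growth`` and shrinks at ``v_shrink`` (µm/min),
    switching growth→shrink with rate ``f_cat`` and shrink→growth with
    rate ``f_res`` (per second of the respective phase).  Position is
    clamped at 0 where a rescue is forced (a microtubule cannot have
    negative length).  Sampled every ``dt`` s with additive Gaussian
    position noise.
    """
    rng = np.random.default_rng(params.seed)
    tracks: list[Track] = []
    n_steps = int(np.floor(params.t_max / params.dt)) + 1
    for _ in range(params.n_tracks):
        times = np.arange(n_steps) * params.dt
        pos = np.empty(n_steps)
        phases = np.empty(n_steps, dtype=object)
        state = "growth"
        x = 0.0
        # next switching time (absolute, s)
        t_switch = (rng.exponential(1.0 / params.f_cat)
                    if params.f_cat > 0 else np.inf)
        t_now = 0.0
        for i in range(n_steps):
            pos[i] = x
            phases[i] = state
            t_next = t_now + params.dt
            # integrate piecewise through any switches inside the step
            while t_switch < t_next:
                v = (params.v_growth if state == "growth"
                     else -params.v_shrink) / 60.0
                x += v * (t_switch - t_now)
                t_now = t_switch
                if state == "growth":
                    state = "shrink"
                    rate = params.f_res
                else:
                    state = "growth"
                    rate = params.f_cat
                t_switch = (t_now + rng.exponential(1.0 / rate)
                            if rate > 0 else np.inf)
            v = (params.v_growth if state == "growth"
                 else -params.v_shrink) / 60.0
            x += v * (t_next - t_now)
            t_now = t_next
            if x <= 0.0:
                x = 0.0
                if state == "shrink":  # forced rescue at zero length
                    state = "growth"
                    t_switch = (t_now + rng.exponential(1.0 / params.f_cat)
                                if params.f_cat > 0 else np.inf)
        if params.position_noise_sd > 0:
            pos = pos + rng.normal(0.0, params.position_noise_sd, n_steps)
        tracks.append(Track(times, pos, frame_interval=params.dt,
                            true_phases=phases))
    return tracks
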