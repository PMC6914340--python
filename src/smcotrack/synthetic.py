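"""Monte-Carlo generator of membrane monomer-dimer dynamics and their
two-color single-molecule localization streams.

The generator emulates what a dual-color TIRF experiment sees when a
receptor population diffuses in the plasma membrane: monomers and dimers
perform 2D Brownian motion (dimers slower, moving as one unit), each
receptor is stochastically labeled with one of two fluorophore species
(or stays dark), and every labeled molecule is rendered per frame as a
localization with Gaussian position error, optional detection dropouts
and irreversible single-step photobleaching.

Two dynamic modes are supported:

``static_fraction``
    a fixed fraction of receptors is paired into dimers at t = 0 and the
    pairing never changes — the regime of a (quasi-)irreversibly
    dimerizing ligand at equilibrium.
``kinetic``
    monomer pairs within a capture radius associate with a per-frame
    probability derived from a 2D association rate constant, and dimers
    dissociate with probability 1 - exp(-k_off * dt) — the dwell time of
    a dimer is the experimental control variable (1/k_off).

Everything is driven by a single seeded :class:`numpy.random.Generator`,
so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LocalizationTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_membrane",
    "render_localizations",
    "simulate_fiducial_beads",
    "simulate_intensity_trace",
    "make_affinity_series",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent or out-of-range simulation parameters."""


@dataclass
class SimulationConfig:
    """Generative parameters of a simulated dual-color movie.

    Defaults reproduce a typical sparse single-molecule TIRF acquisition:
    a 20 x 20 um field of view at 0.5 receptors/um^2, 150 frames at
    32 ms/frame, 25 nm localization precision, and near-balanced two-color
    labeling with a 10% dark fraction.

    Parameters
    ----------
    roi_width_um, roi_height_um : float
        Field-of-view size in micrometres.
    n_receptors : int
        Number of receptor molecules in the ROI.
    d_monomer, d_dimer : float
        Diffusion constants (um^2/s) of monomeric and dimeric receptors.
        Dimers diffuse as a single unit.
    mode : {"static_fraction", "kinetic"}
        Dimerization dynamics (see module docstring).
    dimer_fraction : float
        Fraction of receptor *molecules* residing in dimers (static mode).
    k_on_2d : float
        2D association rate constant (um^2/s), kinetic mode.
    k_off : float
        Dissociation rate (1/s), kinetic mode; dimer dwell time is 1/k_off.
    frame_time_s : float
        Frame interval in seconds.
    n_frames : int
        Movie length in frames.
    p_label_a, p_label_b : float
        Per-receptor probabilities of carrying fluorophore species A or B;
        the remainder stays dark.
    sigma_loc_nm : float
        Isotropic localization error SD per axis (nm).
    detection_eff : float
        Per-frame probability that an active emitter is detected.
    bleach_rate : float
        Per-frame probability that an active fluorophore bleaches
        (irreversible).
    capture_radius_nm : float
        Association capture radius in kinetic mode (simulator knob).
    boundary : {"reflective", "periodic"}
        Boundary handling at the ROI edges.
    seed : int
        RNG seed.
    """

    roi_width_um: float = 20.0
    roi_height_um: float = 20.0
    n_receptors: int = 200
    d_monomer: float = 0.1
    d_dimer: float = 0.05
    mode: str = "static_fraction"
    dimer_fraction: float = 0.0
    k_on_2d: float | None = None
    k_off: float | None = None
    frame_time_s: float = 0.032
    n_frames: int = 150
    p_label_a: float = 0.45
    p_label_b: float = 0.45
    sigma_loc_nm: float = 25.0
    detection_eff: float = 1.0
    bleach_rate: float = 0.0
    capture_radius_nm: float = 100.0
    boundary: str = "reflective"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("static_fraction", "kinetic"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.dimer_fraction <= 1.0):
            raise ConfigurationError("dimer_fraction must be in [0, 1]")
        if self.p_label_a < 0 or self.p_label_b < 0:
            raise ConfigurationError("labeling probabilities must be >= 0")
        if self.p_label_a + self.p_label_b > 1.0 + 1e-12:
            raise ConfigurationError("p_label_a + p_label_b must be <= 1")
        for name in ("roi_width_um", "roi_height_um", "d_monomer", "d_dimer",
                     "frame_time_s", "sigma_loc_nm", "capture_radius_nm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_receptors < 0 or self.n_frames < 1:
            raise ConfigurationError("n_receptors >= 0 and n_frames >= 1 required")
        if not (0.0 <= self.detection_eff <= 1.0):
            raise ConfigurationError("detection_eff must be in [0, 1]")
        if not (0.0 <= self.bleach_rate <= 1.0):
            raise ConfigurationError("bleach_rate must be in [0, 1]")
        if self.boundary not in ("reflective", "periodic"):
            raise ConfigurationError(f"unknown boundary {self.boundary!r}")
        if self.mode == "static_fraction":
            if self.k_on_2d is not None or self.k_off is not None:
                raise ConfigurationError(
                    "kinetic parameters (k_on_2d/k_off) supplied in static mode")
        else:
            if self.k_on_2d is None or self.k_off is None:
                raise ConfigurationError(
                    "kinetic mode requires both k_on_2d and k_off")
            if self.k_on_2d < 0 or self.k_off < 0:
                raise ConfigurationError("rates must be >= 0")


@dataclass
class GroundTruth:
    """True molecular states of a simulated movie.

    Attributes
    ----------
    positions_nm : ndarray, shape (n_frames, n_receptors, 2)
        True (x, y) in nm; paired molecules share identical positions.
    partner : ndarray, shape (n_frames, n_receptors), int
        Partner molecule index per frame, -1 for monomers. Symmetric and
        irreflexive by construction.
    label_species : ndarray, shape (n_receptors,), dtype '<U4'
        "A", "B" or "dark"; filled by :func:`render_localizations`
        (all "dark" before rendering).
    bleach_frame : ndarray, shape (n_receptors,), int
        First frame in which the molecule's fluorophore is bleached;
        ``n_frames`` if it never bleaches.
    config : SimulationConfig
    """

    positions_nm: np.ndarray
    partner: np.ndarray
    label_species: np.ndarray
    bleach_frame: np.ndarray
    config: SimulationConfig

    @property
    def n_frames(self) -> int:
        return self.positions_nm.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.positions_nm.shape[1]

    def dimer_fraction_per_frame(self) -> np.ndarray:
        """Fraction of molecules residing in dimers, per frame."""
        if self.n_receptors == 0:
            return np.zeros(self.n_frames)
        return (self.partner >= 0).mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format per-frame, per-molecule table of the ground truth."""
        nf, nm = self.positions_nm.shape[:2]
        frames = np.repeat(np.arange(nf), nm)
        mol = np.tile(np.arange(nm), nf)
        return pd.DataFrame({
            "frame": frames,
            "molecule_id": mol,
            "partner_id": self.partner.ravel(),
            "true_x_nm": self.positions_nm[:, :, 0].ravel(),
            "true_y_nm": self.positions_nm[:, :, 1].ravel(),
            "label_species": self.label_species[mol],
            "bleached": frames >= self.bleach_frame[mol],
        })


def _apply_boundary(pos: np.ndarray, w_nm: float, h_nm: float,
                    boundary: str) -> np.ndarray:
    if boundary == "periodic":
        pos[:, 0] %= w_nm
        pos[:, 1] %= h_nm
        return pos
    # reflective: fold coordinates back into [0, L] (handles multiple bounces)
    for axis, size in ((0, w_nm), (1, h_nm)):
        x = np.mod(pos[:, axis], 2.0 * size)
        pos[:, axis] = np.where(x > size, 2.0 * size - x, x)
    return pos


def simulate_membrane(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> GroundTruth:
    """Simulate receptor monomer-dimer dynamics on the membrane.

    Each independent diffusing unit (a monomer, or a dimer moving as one
    point) takes Gaussian steps of SD sqrt(2*D*dt) per axis and per frame.
    In kinetic mode, monomer pairs closer than the capture radius
    associate with probability ``1 - exp(-k_on_2d*dt / (pi*r_c^2))`` and
    dimers dissociate with probability ``1 - exp(-k_off*dt)``, both
    evaluated once per frame.

    Parameters
    ----------
    config : SimulationConfig
    rng : numpy.random.Generator, optional
        Overrides ``config.seed`` (used internally for seed policies).

    Returns
    -------
    GroundTruth
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_receptors
    nf = config.n_frames
    w_nm = config.roi_width_um * 1000.0
    h_nm = config.roi_height_um * 1000.0
    dt = config.frame_time_s
    # step SDs in nm: D in um^2/s -> nm^2/s via 1e6
    sd_mono = math.sqrt(2.0 * config.d_monomer * 1e6 * dt)
    sd_dim = math.sqrt(2.0 * config.d_dimer * 1e6 * dt)

    positions = np.empty((nf, n, 2))
    partner_out = np.empty((nf, n), dtype=np.int64)

    pos = np.column_stack([rng.uniform(0, w_nm, n), rng.uniform(0, h_nm, n)])
    partner = np.full(n, -1, dtype=np.int64)

    if config.mode == "static_fraction" and n > 0:
        n_paired = int(round(config.dimer_fraction * n / 2.0)) * 2
        order = rng.permutation(n)
        for i in range(0, n_paired, 2):
            a, b = order[i], order[i + 1]
            partner[a], partner[b] = b, a
            pos[b] = pos[a]

    if config.mode == "kinetic":
        rc = config.capture_radius_nm
        area_c = math.pi * rc * rc
        p_on = 1.0 - math.exp(-config.k_on_2d * 1e6 * dt / area_c) if rc > 0 else 0.0
        p_off = 1.0 - math.exp(-config.k_off * dt)

    for f in range(nf):
        if config.mode == "kinetic" and n > 1:
            # dissociation first, then association, once per frame; freshly
            # dissociated pairs are placed at contact distance and skip
            # association this frame (limits geminate-rebinding bias)
            refractory = np.zeros(n, dtype=bool)
            dimers = np.flatnonzero((partner >= 0) & (np.arange(n) < partner))
            if dimers.size:
                diss = dimers[rng.random(dimers.size) < p_off]
                for a in diss:
                    b = partner[a]
                    partner[a] = partner[b] = -1
                    refractory[a] = refractory[b] = True
                    theta = rng.uniform(0, 2 * math.pi)
                    sep = 0.5 * rc * np.array([math.cos(theta),
                                               math.sin(theta)])
                    mid = pos[a].copy()
                    pos[a] = mid + sep
                    pos[b] = mid - sep
                pos = _apply_boundary(pos, w_nm, h_nm, config.boundary)
            free = np.flatnonzero((partner < 0) & ~refractory)
            if free.size > 1 and p_on > 0.0:
                fpos = pos[free]
                d2 = np.sum((fpos[:, None, :] - fpos[None, :, :]) ** 2, axis=-1)
                iu, ju = np.triu_indices(free.size, k=1)
                close = d2[iu, ju] <= rc * rc
                cand = list(zip(iu[close], ju[close]))
                rng.shuffle(cand)
                for i, j in cand:
                    a, b = free[i], free[j]
                    if partner[a] >= 0 or partner[b] >= 0:
                        continue
                    if rng.random() < p_on:
                        partner[a], partner[b] = b, a
                        mid = 0.5 * (pos[a] + pos[b])
                        pos[a] = pos[b] = mid

        positions[f] = pos
        partner_out[f] = partner

        if f == nf - 1:
            break

        # one Brownian step per independent diffusing unit
        step = np.zeros((n, 2))
        mono = partner < 0
        step[mono] = rng.normal(0.0, sd_mono, (int(mono.sum()), 2))
        leaders = np.flatnonzero((partner >= 0) & (np.arange(n) < partner))
        if leaders.size:
            dstep = rng.normal(0.0, sd_dim, (leaders.size, 2))
            step[leaders] = dstep
            step[partner[leaders]] = dstep
        pos = _apply_boundary(pos + step, w_nm, h_nm, config.boundary)
        # keep partners exactly co-located after boundary folding
        if leaders.size:
            pos[partner[leaders]] = pos[leaders]

    label = np.full(n, "dark", dtype="<U4")
    bleach = np.full(n, nf, dtype=np.int64)
    return GroundTruth(positions, partner_out, label, bleach, config)


def render_localizations(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LocalizationTable, LocalizationTable]:
    """Render a ground truth into two single-channel localization tables.

    Each receptor is assigned once, for the whole movie, to fluorophore
    species A, B or dark with probabilities (p_label_a, p_label_b,
    remainder). Per frame, every labeled molecule whose fluorophore has
    not yet bleached is detected with probability ``detection_eff`` and
    localized at its true position plus isotropic Gaussian error of SD
    ``sigma_loc_nm``. Bleaching is a per-frame Bernoulli event and
    irreversible. Each labeled molecule is rendered as its own emitter;
    co-located same-color labels produce overlapping localizations rather
    than one brighter spot.

    The label assignment and bleach frames are recorded back onto
    ``truth`` (``label_species``, ``bleach_frame``).

    Returns
    -------
    (LocalizationTable, LocalizationTable)
        Channel A and channel B tables.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, nf = truth.n_receptors, truth.n_frames

    u = rng.random(n)
    label = np.full(n, "dark", dtype="<U4")
    label[u < config.p_label_a] = "A"
    label[(u >= config.p_label_a)
          & (u < config.p_label_a + config.p_label_b)] = "B"
    truth.label_species[:] = label

    if config.bleach_rate > 0:
        bleach = rng.geometric(config.bleach_rate, n) - 1  # first bleached frame
    else:
        bleach = np.full(n, nf, dtype=np.int64)
    bleach = np.minimum(bleach, nf)
    truth.bleach_frame[:] = bleach

    frames_idx = np.arange(nf)[:, None]
    active = frames_idx < bleach[None, :]                     # (nf, n)
    labeled = label != "dark"
    detected = active & labeled[None, :]
    if config.detection_eff < 1.0:
        detected &= rng.random((nf, n)) < config.detection_eff

    tables = []
    for species in ("A", "B"):
        mask = detected & (label == species)[None, :]
        f_idx, m_idx = np.nonzero(mask)
        xy = truth.positions_nm[f_idx, m_idx]
        if config.sigma_loc_nm > 0:
            xy = xy + rng.normal(0.0, config.sigma_loc_nm, xy.shape)
        df = pd.DataFrame({
            "frame": f_idx,
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "intensity": np.ones(len(f_idx)),
            "channel": species,
        })
        # both channels are rendered in the same simulation frame, so they
        # are registered by construction
        tables.append(LocalizationTable(df, channel=species, registered=True))
    return tables[0], tables[1]


def simulate_fiducial_beads(
    n_beads: int,
    true_transform=None,
    noise_nm: float = 0.0,
    seed: int = 0,
    roi_nm: tuple[float, float] = (20000.0, 20000.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a multicolor fiducial-bead calibration measurement.

    The same physical bead positions are rendered in both spectral
    channels; channel A is the reference, channel B coordinates are
    mapped through ``true_transform`` (an
    :class:`~smcotrack.registration.AffineTransform2D`, identity if
    None) with Gaussian localization noise of SD ``noise_nm`` added.

    Returns
    -------
    (beads_a, beads_b) : ndarray of shape (n_beads, 2) each
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(0, roi_nm[0], n_beads),
                           rng.uniform(0, roi_nm[1], n_beads)])
    beads_a = pts.copy()
    if true_transform is not None:
        beads_b = true_transform.apply(pts)
    else:
        beads_b = pts.copy()
    if noise_nm > 0:
        beads_b = beads_b + rng.normal(0, noise_nm, beads_b.shape)
    return beads_a, beads_b


def simulate_intensity_trace(
    n_fluorophores: int,
    bleach_rate: float,
    noise_sd: float = 0.0,
    n_frames: int = 150,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a single-emitter intensity trace with stepwise bleaching.

    Each fluorophore contributes unit intensity until its geometric
    bleach time; additive Gaussian noise of SD ``noise_sd`` is applied.
    A dimer carrying two same-color fluorophores yields the classic
    two-step bleaching trace used for stoichiometry counting.
    """
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    rng = np.random.default_rng(seed)
    trace = np.zeros(n_frames)
    for _ in range(n_fluorophores):
        if bleach_rate > 0:
            t_bleach = rng.geometric(bleach_rate)  # active for t_bleach frames
        else:
            t_bleach = n_frames
        trace[: min(t_bleach, n_frames)] += 1.0
    if noise_sd > 0:
        trace = trace + rng.normal(0, noise_sd, n_frames)
    return trace


@dataclass
class Scenario:
    """One labelled condition of an affinity series."""

    label: str
    dimer_fraction: float
    config: SimulationConfig
    truth: GroundTruth
    table_a: LocalizationTable
    table_b: LocalizationTable


def make_affinity_series(
    base_config: SimulationConfig,
    dimer_fractions: Sequence[float],
    labels: Sequence[str] | None = None,
    n_movies: int = 1,
    seed: int | None = None,
) -> list[Scenario]:
    """Generate a ligand-affinity series of simulated scenarios.

    Maps a series of true dimer fractions (mimicking a panel of ligands
    of increasing receptor-dimerization potency) onto independent
    simulations sharing all other parameters with ``base_config``.

    Seed policy: scenario ``i``, movie ``j`` uses a child seed spawned
    deterministically from ``(seed, i, j)`` via ``numpy.random.SeedSequence``,
    so scenarios are independent but the whole series is reproducible
    from one seed.

    Returns a flat list of :class:`Scenario`, ``n_movies`` per fraction,
    in input order.
    """
    for frac in dimer_fractions:
        if not (0.0 <= frac <= 1.0):
            raise ConfigurationError("dimer fractions must be in [0, 1]")
    if labels is None:
        labels = [f"scenario_{i}" for i in range(len(dimer_fractions))]
    if len(labels) != len(dimer_fractions):
        raise ConfigurationError("labels and dimer_fractions length mismatch")
    if seed is None:
        seed = base_config.seed
    out: list[Scenario] = []
    for i, (lab, frac) in enumerate(zip(labels, dimer_fractions)):
        for j in range(n_movies):
            ss = np.random.SeedSequence([seed, i, j])
            cfg = replace(base_config, mode="static_fraction",
                          dimer_fraction=frac, k_on_2d=None, k_off=None,
                          seed=int(ss.generate_state(1)[0] % (2**31)))
            rng = np.random.default_rng(ss)
            truth = simulate_membrane(cfg, rng=rng)
            ta, tb = render_localizations(truth, cfg, rng=rng)
            out.append(Scenario(lab, frac, cfg, truth, ta, tb))
    return out
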