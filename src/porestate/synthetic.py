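"""Synthetic inputs with known ground truth.

Every downstream stage of the package (gate features, pore profiling,
permeation counting, clustering, umbrella-sampling PMFs) is exercised on data
from these generators, whose construction is analytic, so the true answer is
known exactly and is emitted *alongside* the data, never re-derived from it.

The toy channel gate is a marker-atom model of a pseudo-4-fold tetramer: one
backbone marker set (N, CA, C, O, CB) per residue per subunit for the M3 gate
residues 614-625, chi1-defining side-chain atoms at the T617/T625 analogues,
and a short selectivity-filter segment (residues 586-590) below the gate.
Subunits sit at azimuths 0/90/180/270 degrees; a "bent" subunit tilts its
markers above the hinge residue (A618 analogue) radially outward, reproducing
the kinked-M3 signature that widens the upper gate.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._geom import place_zmatrix, wrap_deg
from .io import FrameSeries, StructureModel

__all__ = [
    "ToyGateSpec", "gen_gate_geometry", "gate_frames_from_specs",
    "conductance_standins",
    "ParticleTraceSet", "gen_particle_traces", "write_traces_tsv",
    "AnalyticPotential", "simulate_langevin_1d", "sample_umbrella_windows",
    "gen_state_trajectory",
]

KT_300K = 0.596  # kcal/mol at 300 K

_GATE_RESNAMES = {614: "SER", 615: "LEU", 616: "ALA", 617: "THR", 618: "ALA",
                  619: "PHE", 620: "LEU", 621: "ALA", 622: "VAL", 623: "GLU",
                  624: "ARG", 625: "THR"}
_FILTER_RESNAMES = {586: "GLN", 587: "GLN", 588: "GLY", 589: "CYS", 590: "ASP"}
_CHAINS = ("A", "B", "C", "D")
_RISE = 1.5          # helical rise per residue along z, Angstrom
_HINGE = 618


@dataclass
class ToyGateSpec:
    """Parameters of the marker-atom tetramer gate.

    ``ring_radii`` gives the C-alpha ring radius (Angstrom) at the marker
    residues T617 / A621 / T625; other gate residues interpolate linearly in
    residue number.  ``bend_offset`` is the outward radial displacement of the
    top-gate (T625) markers of a bent subunit; the displacement ramps linearly
    in z from zero at the hinge, producing a genuine kink of angle
    arctan(bend_offset / z-run above the hinge).
    """
    n_subunits: int = 4
    bend_flags: tuple = (False, False, False, False)
    chi1_targets: tuple = (-60.0, -60.0, -60.0, -60.0)   # degrees, T617
    ring_radii: dict = field(default_factory=lambda: {617: 5.0, 621: 5.0, 625: 5.0})
    noise_sd: float = 0.0
    seed: int = 0
    bend_offset: float = 1.5
    filter_radius: float = 3.2

    def validate(self) -> None:
        if self.n_subunits != 4:
            raise ValueError("the toy gate is a tetramer: n_subunits must be 4")
        if len(self.bend_flags) != 4 or len(self.chi1_targets) != 4:
            raise ValueError("bend_flags and chi1_targets need one entry per subunit")
        for a in self.chi1_targets:
            if not (-180.0 < a <= 180.0):
                raise ValueError("chi1 targets must lie in (-180, 180]")
        for r in self.ring_radii.values():
            if r <= 0:
                raise ValueError("ring radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch
    return "C"


def gen_gate_geometry(spec: ToyGateSpec) -> StructureModel:
    """Build the marker-atom tetramer for a :class:`ToyGateSpec`.

    With zero noise the chi1 dihedral recomputed from the generated atoms
    (N-CA-CB-OG1) equals ``chi1_targets`` exactly, diametric C-alpha
    distances equal twice the ring radius, and bent subunits displace the
    T625 marker ring outward by exactly ``bend_offset``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    marker_res = np.array(sorted(spec.ring_radii))
    marker_rad = np.array([spec.ring_radii[r] for r in marker_res], dtype=float)

    rows = []   # (chain, resid, resname, name, xyz)
    z_top = (max(_GATE_RESNAMES) - 625) * _RISE          # z of T625 ring (0.0)
    z_hinge = (_HINGE - 625) * _RISE

    for s, chain in enumerate(_CHAINS):
        phi = np.radians(90.0 * s)
        e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
        e_t = np.array([-np.sin(phi), np.cos(phi), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])

        def residue_atoms(resid, radius, z, chi1=None, with_og1=False):
            ca = radius * e_r + z * e_z
            n = ca - 1.46 * e_z
            c = ca + 1.52 * (0.550 * e_t + 0.835 * e_z)
            o = c + 1.23 * e_r
            cb = ca + 1.53 * (0.898 * e_r + 0.440 * e_z)
            atoms = [("N", n), ("CA", ca), ("C", c), ("O", o), ("CB", cb)]
            if with_og1:
                og1 = place_zmatrix(n, ca, cb, 1.41, 109.5,
                                    chi1 if chi1 is not None else -60.0)
                atoms.append(("OG1", og1))
            # wall markers flanking the C-alpha at +-30 degrees close the
            # pore wall azimuthally (one subunit spans a 90-degree sector)
            for wname, dphi in (("CW1", -np.pi / 6.0), ("CW2", np.pi / 6.0)):
                e_w = np.cos(dphi) * e_r + np.sin(dphi) * e_t
                atoms.append((wname, radius * e_w + z * e_z))
            return atoms

        for resid, resname in _GATE_RESNAMES.items():
            z = (resid - 625) * _RISE
            radius = float(np.interp(resid, marker_res, marker_rad))
            if spec.bend_flags[s] and z > z_hinge:
                radius += spec.bend_offset * (z - z_hinge) / (z_top - z_hinge)
            chi1 = spec.chi1_targets[s] if resid == 617 else None
            atoms = residue_atoms(resid, radius, z,
                                  chi1=chi1, with_og1=(resname == "THR"))
            for name, pos in atoms:
                rows.append((chain, resid, resname, name, pos))

        for resid, resname in _FILTER_RESNAMES.items():
            z = -28.5 + (resid - 586) * _RISE           # below the gate
            atoms = [(nm, pos) for nm, pos
                     in residue_atoms(resid, spec.filter_radius, z)
                     if nm in ("N", "CA", "C", "O", "CW1", "CW2")]
            for name, pos in atoms:
                rows.append((chain, resid, resname, name, pos))

    xyz = np.array([r[4] for r in rows], dtype=float)
    if spec.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, spec.noise_sd, size=xyz.shape)
    return StructureModel(
        chain=np.array([r[0] for r in rows]),
        resid=np.array([r[1] for r in rows], dtype=int),
        resname=np.array([r[2] for r in rows]),
        name=np.array([r[3] for r in rows]),
        element=np.array([_element_of(r[3]) for r in rows]),
        xyz=xyz,
    )


def gate_frames_from_specs(specs, stride_ps: float = 250.0,
                           source: str = "equilibrium") -> FrameSeries:
    """Stack toy-gate models (identical topology) into a FrameSeries."""
    models = [gen_gate_geometry(s) for s in specs]
    coords = np.stack([m.xyz for m in models])
    return FrameSeries(models[0], coords, stride_ps=stride_ps, source=source)


def conductance_standins():
    """Synthetic stand-in structures for the closed / O1 / O2 gate classes.

    The deposited cryo-EM coordinates are not bundled with the package, so
    these *synthetic* tetramers stand in for them: their gate ring radii are
    chosen so the largest inscribed sphere over the gate window falls in the
    middle of each conductance band (closed: about 1.0 A, O1: about 1.9 A,
    O2: about 3.0 A pore radius, i.e. ring radii roughly 1.7 A larger than
    the target, carbon van der Waals).  Returns a list of
    (name, StructureModel, expected_state) tuples.
    """
    cases = [
        ("closed_standin", 2.8, (False, False, False, False), "C"),
        ("o1_standin", 3.6, (False, True, False, True), "O1"),
        ("o2_standin", 4.7, (False, True, False, True), "O2"),
    ]
    out = []
    for name, ring, bends, state in cases:
        spec = ToyGateSpec(bend_flags=bends,
                           ring_radii={617: ring, 621: ring, 625: ring})
        out.append((name, gen_gate_geometry(spec), state))
    return out


# ---------------------------------------------------------------------------
# particle traces with planted crossings
# ---------------------------------------------------------------------------

@dataclass
class ParticleTraceSet:
    """Per-particle z(t) traces with exactly known planted crossing counts.

    A planted downward event descends continuously from the baseline through
    both counting planes and into the lower reservoir; the subsequent return
    to the baseline is a single jump larger than any physical displacement
    (periodic-boundary re-entry) that the counter must ignore.  Distractor
    excursions dip below the entry plane but never reach the exit plane.
    """
    times_ps: np.ndarray            # (n_t,)
    z: np.ndarray                   # (n_particles, n_t) Angstrom
    planted_downward: int
    planted_upward: int
    planted_distractors: int
    per_particle_down: np.ndarray   # (n_particles,)
    per_particle_up: np.ndarray
    duration_ns: float = 0.0
    stride_ps: float = 10.0
    entry_z: float = -6.0
    exit_z: float = -16.0

    @property
    def n_particles(self) -> int:
        return self.z.shape[0]


def _event_shape(kind: str, f: np.ndarray, baseline: float) -> np.ndarray:
    """Piecewise-linear z as a function of window fraction f in [0, 1]."""
    z = np.empty_like(f)
    if kind == "down":
        a = f < 0.5
        b = (f >= 0.5) & (f < 0.75)
        z[a] = baseline - (baseline + 20.0) * (f[a] / 0.5)
        z[b] = -20.0 - 40.0 * (f[b] - 0.5)
        z[~a & ~b] = -30.0
    elif kind == "up":
        a = f < 0.25
        b = (f >= 0.25) & (f < 0.75)
        z[a] = -30.0
        z[b] = -30.0 + 26.0 * (f[b] - 0.25) / 0.5
        c = ~a & ~b
        z[c] = -4.0 + (baseline + 4.0) * (f[c] - 0.75) / 0.25
    elif kind == "distractor":
        a = f < 0.5
        z[a] = baseline - (baseline + 11.0) * (f[a] / 0.5)
        z[~a] = -11.0 + (baseline + 11.0) * (f[~a] - 0.5) / 0.5
    else:
        raise ValueError(kind)
    return z


def gen_particle_traces(n_particles: int, rate_down: float, rate_up: float,
                        duration_ns: float, stride_ps: float = 10.0,
                        seed: int = 0, distractor_rate: float | None = None,
                        passage_ps: float = 200.0, jitter_sd: float = 0.15,
                        entry_z: float = -6.0, exit_z: float = -16.0) -> ParticleTraceSet:
    """Generate z-traces with Poisson-planted directional crossings.

    Event counts per particle are Poisson with mean rate x duration; the
    planted totals are recorded exactly.  ``distractor_rate`` defaults to the
    total crossing rate, exercising the counter's rejection path.
    """
    if rate_down < 0 or rate_up < 0:
        raise ValueError("crossing rates must be non-negative")
    if duration_ns <= 0 or stride_ps <= 0:
        raise ValueError("duration and stride must be positive")
    n_t = int(round(duration_ns * 1000.0 / stride_ps))
    if abs(n_t * stride_ps - duration_ns * 1000.0) > 1e-6:
        raise ValueError("stride must divide the duration")
    if distractor_rate is None:
        distractor_rate = rate_down + rate_up

    rng = np.random.default_rng(seed)
    times = np.arange(n_t) * stride_ps
    baseline = 2.0
    w_samp = max(int(round(passage_ps / stride_ps)), 8)
    w_ps = w_samp * stride_ps

    z = np.full((n_particles, n_t), baseline, dtype=float)
    n_down = rng.poisson(rate_down * duration_ns, size=n_particles)
    n_up = rng.poisson(rate_up * duration_ns, size=n_particles)
    n_dis = rng.poisson(distractor_rate * duration_ns, size=n_particles)

    for p in range(n_particles):
        kinds = (["down"] * n_down[p] + ["up"] * n_up[p]
                 + ["distractor"] * n_dis[p])
        n_ev = len(kinds)
        if n_ev == 0:
            continue
        slot = w_ps + stride_ps                 # one-stride guard between events
        free = duration_ns * 1000.0 - n_ev * slot
        if free < 0:
            raise ValueError("rates too high for the requested duration: "
                             "events do not fit without overlap")
        rng.shuffle(kinds)
        offsets = np.sort(rng.uniform(0.0, free, size=n_ev))
        starts = offsets + np.arange(n_ev) * slot
        for s, kind in zip(starts, kinds):
            k0 = int(np.ceil(s / stride_ps))
            k1 = min(int(np.floor((s + w_ps) / stride_ps)), n_t - 1)
            f = (times[k0:k1 + 1] - s) / w_ps
            z[p, k0:k1 + 1] = _event_shape(kind, f, baseline)

    if jitter_sd > 0:
        z += rng.normal(0.0, jitter_sd, size=z.shape)

    return ParticleTraceSet(
        times_ps=times, z=z,
        planted_downward=int(n_down.sum()), planted_upward=int(n_up.sum()),
        planted_distractors=int(n_dis.sum()),
        per_particle_down=n_down, per_particle_up=n_up,
        duration_ns=duration_ns, stride_ps=stride_ps,
        entry_z=entry_z, exit_z=exit_z)


def write_traces_tsv(traces: ParticleTraceSet, path, ground_truth_path=None) -> None:
    """Write traces as TSV (particle_id, time_ps, z_angstrom) plus a sidecar
    JSON with the planted ground truth."""
    with open(path, "w") as fh:
        fh.write("particle_id\ttime_ps\tz_angstrom\n")
        for p in range(traces.n_particles):
            for t, zz in zip(traces.times_ps, traces.z[p]):
                fh.write(f"{p}\t{t:.3f}\t{zz:.4f}\n")
    if ground_truth_path is not None:
        truth = {
            "planted_downward": traces.planted_downward,
            "planted_upward": traces.planted_upward,
            "planted_distractors": traces.planted_distractors,
            "duration_ns": traces.duration_ns,
            "entry_z": traces.entry_z,
            "exit_z": traces.exit_z,
        }
        with open(ground_truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------------
# 1-D potentials and overdamped Langevin sampling
# ---------------------------------------------------------------------------

@dataclass
class AnalyticPotential:
    """1-D potential with closed-form energy and gradient (kcal/mol, Angstrom).

    Forms: ``flat`` (U = 0), ``harmonic`` (U = a z^2 / 2, parameter ``a``) and
    ``double_well`` (U = barrier ((z/half_sep)^2 - 1)^2: minima at
    +-half_sep, barrier height exactly ``barrier`` at z = 0).
    """
    form: str = "flat"
    params: dict = field(default_factory=dict)
    kT: float = KT_300K

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            u = np.zeros_like(z)
        elif self.form == "harmonic":
            u = 0.5 * self.params["a"] * z ** 2
        elif self.form == "double_well":
            b, z0 = self.params["barrier"], self.params.get("half_sep", 1.0)
            u = b * ((z / z0) ** 2 - 1.0) ** 2
        else:
            raise ValueError(f"unknown potential form: {self.form!r}")
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("potential is not finite on the input")
        return u

    def grad(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "harmonic":
            return self.params["a"] * z
        if self.form == "double_well":
            b, z0 = self.params["barrier"], self.params.get("half_sep", 1.0)
            return 4.0 * b * z * ((z / z0) ** 2 - 1.0) / z0 ** 2
        raise ValueError(f"unknown potential form: {self.form!r}")

    def max_curvature(self, half_domain: float = 4.0) -> float:
        if self.form == "flat":
            return 0.0
        if self.form == "harmonic":
            return float(self.params["a"])
        if self.form == "double_well":
            b, z0 = self.params["barrier"], self.params.get("half_sep", 1.0)
            zm = min(half_domain, 2.0 * z0)
            return float(b * (12.0 * zm ** 2 / z0 ** 4 - 4.0 / z0 ** 2))
        raise ValueError(f"unknown potential form: {self.form!r}")


def _check_dt(potential: AnalyticPotential, bias_k: float, dt: float) -> None:
    k_eff = bias_k + max(potential.max_curvature(), 0.0)
    if k_eff > 0 and dt * k_eff >= 1.0:
        raise ValueError(
            f"overdamped Euler-Maruyama unstable: dt * max stiffness = "
            f"{dt * k_eff:.3g} >= 1; reduce dt")


def simulate_langevin_1d(potential: AnalyticPotential, bias_center: float = 0.0,
                         bias_k: float = 0.0, n_steps: int = 100000,
                         dt: float = 1e-3, seed: int = 0,
                         z_init: float | None = None,
                         kT: float | None = None) -> np.ndarray:
    """Overdamped Euler-Maruyama sampling of U(z) + harmonic bias.

    Unit mobility, reduced time: dz = -(U' + k (z - c)) dt + sqrt(2 kT dt) xi.
    The stationary law converges to exp(-(U + bias)/kT) as dt -> 0; the
    stability condition dt * (max curvature) < 1 is enforced.
    Returns the position after every step (length ``n_steps``).
    """
    kT = potential.kT if kT is None else kT
    _check_dt(potential, bias_k, dt)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps) * np.sqrt(2.0 * kT * dt)
    z = float(bias_center if z_init is None else z_init)
    out = np.empty(n_steps)
    grad = potential.grad
    for i in range(n_steps):
        g = float(grad(z)) + bias_k * (z - bias_center)
        z = z - g * dt + noise[i]
        out[i] = z
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("Langevin trajectory diverged")
    return out


def sample_umbrella_windows(potential: AnalyticPotential, anchors,
                            spring_k: float = 25.0, n_samples: int = 3000,
                            thin: int = 10, burn_in: int = 2000,
                            dt: float = 1e-3, seed: int = 0,
                            kT: float | None = None):
    """Langevin-sample every umbrella window (vectorised across windows).

    Anchors follow the study layout: 0.4-Angstrom spacing with a 25
    kcal/mol/A^2 spring by default.  Returns a list of
    :class:`porestate.pmf.UmbrellaWindow`.
    """
    from .pmf import UmbrellaWindow
    kT = potential.kT if kT is None else kT
    _check_dt(potential, spring_k, dt)
    anchors = np.asarray(anchors, dtype=float)
    rng = np.random.default_rng(seed)
    z = anchors.copy()
    sig = np.sqrt(2.0 * kT * dt)
    samples = np.empty((len(anchors), n_samples))
    n_total = burn_in + n_samples * thin
    j = 0
    for i in range(n_total):
        g = potential.grad(z) + spring_k * (z - anchors)
        z = z - g * dt + sig * rng.standard_normal(len(anchors))
        if i >= burn_in and (i - burn_in) % thin == thin - 1:
            samples[:, j] = z
            j += 1
    if not np.all(np.isfinite(samples)):
        raise FloatingPointError("umbrella sampling diverged")
    return [UmbrellaWindow(anchor=float(a), spring_k=spring_k,
                           samples=samples[i].copy())
            for i, a in enumerate(anchors)]


# ---------------------------------------------------------------------------
# Markov state trajectories in feature space
# ---------------------------------------------------------------------------

def gen_state_trajectory(state_centroids, transition_matrix, n_frames: int,
                         noise, angle_mask, seed: int = 0):
    """Markov-switching feature trajectory with per-frame true labels.

    ``state_centroids`` is (n_states, n_features); ``angle_mask`` marks
    angular features (degrees): their noise is applied on the circle, so a
    centroid at 179 degrees emits values near -179 as well.  Returns
    (features, labels).
    """
    C = np.asarray(state_centroids, dtype=float)
    T = np.asarray(transition_matrix, dtype=float)
    n_states, n_feat = C.shape
    if T.shape != (n_states, n_states):
        raise ValueError("transition matrix shape must match the state count")
    if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must be stochastic (sum to 1)")
    angle_mask = np.asarray(angle_mask, dtype=bool)
    if angle_mask.shape != (n_feat,):
        raise ValueError("angle_mask must have one flag per feature")
    if np.any((C[:, angle_mask] <= -180.0) | (C[:, angle_mask] > 180.0)):
        raise ValueError("centroid angles must lie in (-180, 180]")
    noise = np.broadcast_to(np.asarray(noise, dtype=float), (n_feat,))

    rng = np.random.default_rng(seed)
    labels = np.empty(n_frames, dtype=int)
    labels[0] = rng.integers(n_states)
    cum = np.cumsum(T, axis=1)
    u = rng.random(n_frames)
    for i in range(1, n_frames):
        labels[i] = int(np.searchsorted(cum[labels[i - 1]], u[i]))
    feats = C[labels] + rng.normal(0.0, 1.0, size=(n_frames, n_feat)) * noise
    feats[:, angle_mask] = wrap_deg(feats[:, angle_mask])
    return feats, labels
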