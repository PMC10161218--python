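"""Seeded generators for every input the analysis consumes.

Each generator is a bit-exact function of its parameters and seed and
returns its ground truth alongside the data, so every pipeline stage can be
exercised end-to-end without external data:

* T-jump ladders: D/A relaxation traces simulated from the same
  finite-difference two-state amplitude model the melting fit assumes;
* FRAP traces: single-exponential recovery with a known mobile fraction;
* two-channel focus fields: PSF-blurred disks with a planted area-overlap
  fraction, plus partition-coefficient images with planted PC;
* toy CAG hairpins: idealized helical coordinates with the canonical
  C-G / G-C pairing scheme (A-A mismatches, two-repeat terminal loop) and
  optional ATP molecules planted at hydrogen-bond geometry;
* Gaussian group samples for the ANOVA/Tukey layer.

The hairpin geometry is decorative — a regular helix (rise 0.28 nm, twist
32.7 deg per residue step) carrying chemically labelled atoms — sufficient
for geometric and contact-counting tests, with no energetic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import thermo
from .contacts import Topology, Trajectory, classify_moieties
from .frap import FRAPTrace
from .imaging import ChannelImage
from .tjump import AmplitudeCurve, JumpProtocol, RelaxationTrace
from .thermo import MeltingParameters

__all__ = [
    "NoiseSpec", "TJumpExperiment", "gen_amplitude_curve", "gen_tjump_experiment",
    "gen_frap_trace", "FociField", "gen_foci_images", "gen_partition_image",
    "HairpinModel", "gen_cag_hairpin", "plant_atp", "gen_atp_binding_trajectory",
    "gen_groups", "load_lm4u_star",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise level (fraction of signal) + RNG seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# --- temperature-jump ladders --------------------------------------------

def _true_amplitudes(params: MeltingParameters, protocol: JumpProtocol,
                     c: float, drift: float) -> np.ndarray:
    t_post = np.asarray(protocol.target_temperatures)
    t_prev = np.concatenate(([protocol.start_temperature], t_post[:-1]))
    fu = lambda T: np.asarray(thermo.unfolded_fraction(params.g1 * (T - params.tm), T))
    return c * (fu(t_post) - fu(t_prev)) + drift * (t_post - t_prev)


def gen_amplitude_curve(params: MeltingParameters, protocol: JumpProtocol,
                        noise: NoiseSpec = NoiseSpec(), c: float = 1.0,
                        drift: float = 0.0) -> AmplitudeCurve:
    """Amplitude-versus-temperature curve from the two-state model.

    Noise is additive Gaussian with sigma = ``noise.sigma`` x max |amplitude|
    (the per-point amplitude uncertainty of a real ladder).
    """
    a = _true_amplitudes(params, protocol, c, drift)
    scale = float(np.max(np.abs(a))) or 1.0
    sig = noise.sigma * scale
    if sig > 0:
        a = a + noise.rng().normal(0.0, sig, size=a.shape)
    return AmplitudeCurve(np.asarray(protocol.target_temperatures), a,
                          np.full(a.shape, sig), protocol.start_temperature)


@dataclass
class TJumpExperiment:
    """Simulated ladder: per-jump traces + the generating truth."""

    traces: list
    protocol: JumpProtocol
    true_params: MeltingParameters
    true_curve: AmplitudeCurve
    scale: float
    drift: float


def gen_tjump_experiment(params: MeltingParameters, protocol: JumpProtocol,
                         noise: NoiseSpec = NoiseSpec(), c: float = 1.0,
                         drift: float = 0.0, base_ratio: float = 0.6,
                         acceptor_level: float = 1000.0, k0: float = 1.0,
                         arrhenius_slope: float = 0.02,
                         dt: float = 0.1) -> TJumpExperiment:
    """Simulate a full consecutive-jump FRET experiment.

    Per jump k the D/A ratio relaxes as r(t) = r_{k-1} + a_k (1 - e^{-k_obs t})
    with a_k from the finite-difference two-state model (scale ``c``, linear
    drift ``drift`` per K) and an Arrhenius-like rate schedule
    k_obs(T) = k0 * exp(arrhenius_slope * (T - 310)).  Donor and acceptor
    channels carry independent multiplicative Gaussian noise of fractional
    width ``noise.sigma``.
    """
    temps = np.asarray(protocol.target_temperatures)
    if temps.size < 2:
        raise ValueError("degenerate protocol: need at least 2 jump temperatures")
    if np.any(temps <= 273.0) or np.any(temps >= 373.0):
        raise ValueError("jump temperatures must lie in (273, 373) K")

    rng = noise.rng()
    a_true = _true_amplitudes(params, protocol, c, drift)
    t_prev = np.concatenate(([protocol.start_temperature], temps[:-1]))
    fu0 = thermo.unfolded_fraction(params.g1 * (t_prev[0] - params.tm), t_prev[0])

    # first sample coincides with the jump onset (t = 0)
    time = np.arange(0.0, protocol.dwell_per_jump + dt / 2, dt)
    traces = []
    for k, (tp, tk, ak) in enumerate(zip(t_prev, temps, a_true)):
        fu_prev = thermo.unfolded_fraction(params.g1 * (tp - params.tm), tp)
        r0 = base_ratio + c * (fu_prev - fu0) + drift * (tp - t_prev[0])
        k_obs = k0 * np.exp(arrhenius_slope * (tk - 310.0))
        ratio = r0 + ak * (1.0 - np.exp(-k_obs * time))
        acceptor = acceptor_level * (1.0 + rng.normal(0, noise.sigma, time.shape))
        donor = acceptor_level * ratio * (1.0 + rng.normal(0, noise.sigma, time.shape))
        traces.append(RelaxationTrace(time=time, donor=np.abs(donor),
                                      acceptor=np.abs(acceptor),
                                      pre_jump_T=float(tp), post_jump_T=float(tk)))
    true_curve = AmplitudeCurve(temps, a_true, np.zeros_like(a_true),
                                protocol.start_temperature)
    return TJumpExperiment(traces=traces, protocol=protocol, true_params=params,
                           true_curve=true_curve, scale=c, drift=drift)


# --- FRAP ----------------------------------------------------------------

def gen_frap_trace(f_mobile: float, tau: float, bleach_depth: float,
                   noise: NoiseSpec = NoiseSpec(), n_pre: int = 5,
                   n_post: int = 80, dt: float = 0.5,
                   baseline: float = 5000.0) -> tuple:
    """Single-exponential FRAP recovery with planted (f_mobile, tau).

    Returns ``(FRAPTrace, truth_dict)``.  ``bleach_depth`` is 1 - I0 of the
    normalized trace; noise sigma is a fraction of the pre-bleach level.
    """
    if not 0.0 <= f_mobile <= 1.0:
        raise ValueError("f_mobile must be in [0, 1]")
    if not 0.05 < bleach_depth < 1.0:
        raise ValueError("bleach_depth must be in (0.05, 1)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = noise.rng()
    t_pre = np.arange(n_pre) * dt
    t_post = t_pre[-1] + dt + np.arange(n_post) * dt
    i0 = 1.0 - bleach_depth
    plateau = i0 + f_mobile * bleach_depth
    pre = np.ones(n_pre)
    post = i0 + (plateau - i0) * (1.0 - np.exp(-(t_post - t_post[0]) / tau))
    y = np.concatenate([pre, post])
    y = baseline * (y + rng.normal(0.0, noise.sigma, y.shape))
    trace = FRAPTrace(time=np.concatenate([t_pre, t_post]),
                      roi_intensity=np.abs(y), bleach_index=n_pre)
    return trace, {"f_mobile": f_mobile, "tau": tau, "bleach_depth": bleach_depth}


# --- two-channel focus fields --------------------------------------------

def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _render_foci(shape, centers, radius, amplitude, sigma):
    """Disks of the truth geometry blurred by a Gaussian PSF."""
    from scipy.ndimage import gaussian_filter
    img = np.zeros(shape)
    for c in centers:
        img[_disk_mask(shape, c, radius)] = amplitude
    return gaussian_filter(img, sigma)


@dataclass
class FociField:
    """Synthetic two-channel field with its planted ground truth."""

    rna: ChannelImage
    speckle: ChannelImage
    rna_truth_mask: np.ndarray
    speckle_truth_mask: np.ndarray
    true_overlap_fraction: float
    rna_centers: list
    speckle_centers: list


def gen_foci_images(n_rna_foci: int = 20, n_speckles: int = 12,
                    overlap_area_fraction: float = 0.45,
                    psf_sigma: float = 1.5, noise: NoiseSpec = NoiseSpec(),
                    shape: tuple = (256, 256), rna_radius: int = 3,
                    speckle_radius: int = 9, amplitude: float = 400.0,
                    background: float = 20.0) -> FociField:
    """Plant RNA foci so a requested area fraction lies on speckles.

    A ``round(overlap_area_fraction * n_rna_foci)`` subset of identical RNA
    foci is placed fully inside speckles and the rest fully outside, making
    the planted area-overlap fraction equal to the requested one up to the
    1-px rounding of identical truth disks.  Intensities get Poisson photon
    noise plus additive Gaussian noise of width ``noise.sigma * amplitude``.
    """
    if not 0.0 <= overlap_area_fraction <= 1.0:
        raise ValueError("overlap_area_fraction must be in [0, 1]")
    rng = noise.rng()
    margin = speckle_radius + 4

    def _place(n, min_sep, avoid=(), avoid_dist=0.0, inside=None, max_tries=20000):
        centers = []
        tries = 0
        while len(centers) < n:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("infeasible focus packing; reduce counts or radii")
            if inside is not None:
                # one RNA focus per host speckle, offset within its interior
                base = inside[len(centers)]
                max_off = speckle_radius - rna_radius - 3
                off = rng.uniform(-max_off, max_off, 2)
                if np.hypot(*off) > max_off:
                    continue
                cand = (base[0] + off[0], base[1] + off[1])
            else:
                cand = (rng.uniform(margin, shape[0] - margin),
                        rng.uniform(margin, shape[1] - margin))
            if any(np.hypot(cand[0] - c[0], cand[1] - c[1]) < min_sep for c in centers):
                continue
            if any(np.hypot(cand[0] - c[0], cand[1] - c[1]) < avoid_dist for c in avoid):
                continue
            centers.append(cand)
        return centers

    n_inside = int(round(overlap_area_fraction * n_rna_foci))
    if n_inside > n_speckles:
        raise RuntimeError("infeasible packing: need n_speckles >= "
                           f"{n_inside} host speckles for the requested overlap")
    speckle_centers = _place(n_speckles, 2 * speckle_radius + 6)
    host_order = noise.rng().permutation(n_speckles)
    inside_centers = _place(n_inside, 2 * rna_radius + 2,
                            inside=[speckle_centers[i] for i in host_order])
    outside_centers = _place(n_rna_foci - n_inside, 2 * rna_radius + 2,
                             avoid=speckle_centers,
                             avoid_dist=speckle_radius + rna_radius + 4)
    rna_centers = inside_centers + outside_centers

    rna_truth = np.zeros(shape, dtype=bool)
    for c in rna_centers:
        rna_truth |= _disk_mask(shape, c, rna_radius)
    speckle_truth = np.zeros(shape, dtype=bool)
    for c in speckle_centers:
        speckle_truth |= _disk_mask(shape, c, speckle_radius)
    true_frac = float((rna_truth & speckle_truth).sum() / rna_truth.sum()) \
        if rna_truth.any() else float("nan")

    def _noisy(img):
        img = rng.poisson(img).astype(float)
        if noise.sigma > 0:
            img = img + rng.normal(0.0, noise.sigma * amplitude, img.shape)
        return np.clip(img, 0.0, None)

    rna_img = _noisy(background + _render_foci(shape, rna_centers, rna_radius,
                                               amplitude, psf_sigma))
    sp_img = _noisy(background + _render_foci(shape, speckle_centers, speckle_radius,
                                              amplitude, psf_sigma))
    return FociField(
        rna=ChannelImage(rna_img, channel_name="rna"),
        speckle=ChannelImage(sp_img, channel_name="speckle"),
        rna_truth_mask=rna_truth, speckle_truth_mask=speckle_truth,
        true_overlap_fraction=true_frac,
        rna_centers=rna_centers, speckle_centers=speckle_centers)


def gen_partition_image(pc: float = 2.5, noise: NoiseSpec = NoiseSpec(),
                        shape: tuple = (192, 192), n_speckles: int = 5,
                        speckle_radius: int = 12,
                        nucleoplasm_level: float = 200.0) -> tuple:
    """Image with planted speckle/nucleoplasm intensity ratio ``pc``.

    Returns ``(ChannelImage, speckle_mask, nucleus_mask, truth_dict)``;
    intensities carry Poisson noise (plus optional Gaussian noise).
    """
    if pc <= 0:
        raise ValueError("partition coefficient must be positive")
    rng = noise.rng()
    nucleus = _disk_mask(shape, (shape[0] / 2, shape[1] / 2), min(shape) / 2 - 8)
    speckle = np.zeros(shape, dtype=bool)
    cx, cy = shape[0] / 2, shape[1] / 2
    for k in range(n_speckles):
        ang = 2 * np.pi * k / n_speckles + rng.uniform(0, 0.5)
        rad = rng.uniform(0.3, 0.6) * (min(shape) / 2 - 8 - speckle_radius)
        speckle |= _disk_mask(shape, (cx + rad * np.sin(ang), cy + rad * np.cos(ang)),
                              speckle_radius)
    speckle &= nucleus
    img = np.zeros(shape)
    img[nucleus] = nucleoplasm_level
    img[speckle] = nucleoplasm_level * pc
    img = rng.poisson(img).astype(float)
    if noise.sigma > 0:
        img = np.clip(img + rng.normal(0, noise.sigma * nucleoplasm_level, shape),
                      0, None)
    return (ChannelImage(img, channel_name="rna"), speckle, nucleus,
            {"pc": pc, "nucleoplasm_level": nucleoplasm_level})


# --- toy CAG hairpin / ATP geometry --------------------------------------

# local nucleotide template, nm, ribose pentagon in the xy plane at C1'=origin
_SUGAR_TEMPLATE = {
    "C1'": (0.00, 0.00, 0.00), "O4'": (0.07, 0.12, 0.00),
    "C4'": (0.21, 0.08, 0.00), "C3'": (0.23, -0.07, 0.00),
    "C2'": (0.10, -0.12, 0.00), "O2'": (0.10, -0.26, 0.02),
    "HO2'": (0.18, -0.31, 0.02), "C5'": (0.33, 0.17, 0.02),
    "O5'": (0.46, 0.10, 0.02), "P": (0.59, 0.19, 0.00),
    "OP1": (0.67, 0.14, 0.11), "OP2": (0.67, 0.14, -0.11),
    "O3'": (0.36, -0.14, 0.00),
}

# planar base templates in (u, v) ring coordinates relative to the
# glycosidic nitrogen; embedded on a tilted plane so chi is non-degenerate
_BASE_2D = {
    "A": {"N9": (0.00, 0.00), "C4": (-0.135, 0.03), "N3": (-0.22, 0.14),
          "C2": (-0.35, 0.11), "N1": (-0.39, -0.02), "C6": (-0.31, -0.13),
          "N6": (-0.36, -0.26), "H61": (-0.30, -0.34), "H62": (-0.45, -0.28),
          "C5": (-0.175, -0.10), "N7": (-0.065, -0.175), "C8": (0.06, -0.12)},
    "G": {"N9": (0.00, 0.00), "C4": (-0.135, 0.03), "N3": (-0.22, 0.14),
          "C2": (-0.35, 0.11), "N2": (-0.43, 0.21), "H21": (-0.38, 0.29),
          "H22": (-0.53, 0.20), "N1": (-0.39, -0.02), "H1": (-0.49, -0.04),
          "C6": (-0.31, -0.13), "O6": (-0.36, -0.26),
          "C5": (-0.175, -0.10), "N7": (-0.065, -0.175), "C8": (0.06, -0.12)},
    "C": {"N1": (0.00, 0.00), "C2": (-0.13, 0.05), "O2": (-0.16, 0.18),
          "N3": (-0.24, -0.04), "C4": (-0.22, -0.17), "N4": (-0.33, -0.26),
          "H41": (-0.31, -0.36), "H42": (-0.43, -0.23),
          "C5": (-0.09, -0.22), "C6": (0.02, -0.13)},
    "U": {"N1": (0.00, 0.00), "C2": (-0.13, 0.05), "O2": (-0.16, 0.18),
          "N3": (-0.24, -0.04), "H3": (-0.34, -0.06), "C4": (-0.22, -0.17),
          "O4": (-0.32, -0.25), "C5": (-0.09, -0.22), "C6": (0.02, -0.13)},
}

_GLYCOSIDIC_OFFSET = np.array([-0.14, -0.02, 0.03])
_BASE_EU = np.array([-0.96, 0.00, 0.28])   # tilted base-plane axes
_BASE_EV = np.array([0.00, 0.97, 0.25])


def _nucleotide_atoms(res: str) -> list:
    """(atom_name, element, xyz) template for one nucleotide, nm."""
    out = []
    for name, xyz in _SUGAR_TEMPLATE.items():
        elem = "H" if name.startswith("H") else name[0]
        out.append((name, elem, np.array(xyz)))
    n_gly = _GLYCOSIDIC_OFFSET
    for name, (u, v) in _BASE_2D[res].items():
        elem = "H" if name.startswith("H") else name[0]
        out.append((name, elem, n_gly + u * _BASE_EU + v * _BASE_EV))
    return out


_ATP_PHOSPHATES = [
    ("PA", "P", (0.74, 0.16, 0.00)), ("O1A", "O", (0.80, 0.28, 0.05)),
    ("O2A", "O", (0.80, 0.05, -0.08)), ("O3A", "O", (0.88, 0.20, 0.08)),
    ("PB", "P", (1.02, 0.24, 0.02)), ("O1B", "O", (1.08, 0.36, 0.08)),
    ("O2B", "O", (1.08, 0.13, -0.06)), ("O3B", "O", (1.16, 0.28, 0.10)),
    ("PG", "P", (1.30, 0.32, 0.04)), ("O1G", "O", (1.36, 0.44, 0.10)),
    ("O2G", "O", (1.36, 0.21, -0.04)), ("O3G", "O", (1.42, 0.36, 0.12)),
]


def _atp_atoms() -> list:
    """ATP template: adenine + ribose (with O3'H) + triphosphate tail."""
    out = []
    for name, xyz in _SUGAR_TEMPLATE.items():
        if name in ("P", "OP1", "OP2"):
            continue
        elem = "H" if name.startswith("H") else name[0]
        out.append((name, elem, np.array(xyz)))
    out.append(("HO3'", "H", np.array(_SUGAR_TEMPLATE["O3'"]) + (0.05, -0.08, 0.02)))
    for name, (u, v) in _BASE_2D["A"].items():
        elem = "H" if name.startswith("H") else name[0]
        out.append((name, elem, _GLYCOSIDIC_OFFSET + u * _BASE_EU + v * _BASE_EV))
    for name, elem, xyz in _ATP_PHOSPHATES:
        out.append((name, elem, np.array(xyz)))
    return out


@dataclass
class Pair:
    """One pairing-scheme entry (1-based nucleotide indices)."""

    i: int
    j: int
    kind: str   # "canonical" (C-G/G-C) or "mismatch" (A-A)


@dataclass
class HairpinModel:
    """Idealized (CAG)_n hairpin: sequence, pairing scheme, toy coordinates."""

    sequence: str
    pairs: list
    trajectory: Trajectory
    n_repeats: int

    @property
    def n_canonical_pairs(self) -> int:
        return sum(1 for p in self.pairs if p.kind == "canonical")


_HELIX_RISE = 0.28      # nm per residue step
_HELIX_TWIST = 32.7     # deg per residue step
_HELIX_RADIUS = 0.9     # nm


def gen_cag_hairpin(n_repeats: int) -> HairpinModel:
    """Idealized (CAG)_n hairpin with the repeat-register pairing scheme.

    Repeats i and n+1-i pair for i = 1..floor((n-2)/2), leaving a two-repeat
    (6-nt) terminal loop.  Within a repeat pair, C-G and G-C are canonical
    and A-A is a mismatch, so the canonical pair count is 2*floor((n-2)/2)
    (18 for n = 20).  Coordinates are a regular helix for the 5' arm, a loop
    arc, and the 3' arm returning alongside — geometric scaffolding only.
    """
    if n_repeats < 4 or n_repeats % 2:
        raise ValueError("n_repeats must be even and >= 4")
    seq = "CAG" * n_repeats
    n_nt = 3 * n_repeats

    pairs = []
    for r in range(1, (n_repeats - 2) // 2 + 1):
        rp = n_repeats + 1 - r
        c_i, a_i, g_i = 3 * r - 2, 3 * r - 1, 3 * r
        c_j, a_j, g_j = 3 * rp - 2, 3 * rp - 1, 3 * rp
        pairs.append(Pair(c_i, g_j, "canonical"))
        pairs.append(Pair(g_i, c_j, "canonical"))
        pairs.append(Pair(a_i, a_j, "mismatch"))

    half = n_nt // 2
    names, elements, resnames, resids, coords = [], [], [], [], []
    for idx in range(n_nt):
        res = seq[idx]
        if idx < half:                      # 5' arm, ascending helix
            step, strand = idx, 0
        else:                               # 3' arm, descending on the far side
            step, strand = n_nt - 1 - idx, 1
        ang = np.radians(_HELIX_TWIST * step + 180.0 * strand)
        origin = np.array([_HELIX_RADIUS * np.cos(ang),
                           _HELIX_RADIUS * np.sin(ang),
                           _HELIX_RISE * step])
        # rotate the template about z with the helix, flip the 3' strand
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        if strand:
            rot = rot @ np.diag([1.0, -1.0, -1.0])
        for name, elem, xyz in _nucleotide_atoms(res):
            names.append(name)
            elements.append(elem)
            resnames.append(res)
            resids.append(idx + 1)
            coords.append(origin + rot @ xyz)

    top = Topology(atom_name=names, residue_name=resnames, residue_index=resids,
                   chain_id=["R"] * len(names), element=elements)
    traj = Trajectory(topology=top, coords=np.asarray(coords)[None, :, :])
    classify_moieties(top)   # every heavy atom must classify; raises otherwise
    return HairpinModel(sequence=seq, pairs=pairs, trajectory=traj,
                        n_repeats=n_repeats)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def plant_atp(hairpin: HairpinModel, target_residue: int, target_atom: str,
              distance: float = 0.29, angle_deg: float = 175.0) -> Trajectory:
    """Append one ATP with its N6-H61 donor hydrogen-bonded to a target atom.

    The ATP adenine N6 is placed ``distance`` nm from the target acceptor
    along the outward direction (away from the local RNA crowd), with the
    H61 bond aimed at the acceptor and the whole molecule tilted so the
    D-H...A angle equals ``angle_deg``.  Returns a new single-frame
    Trajectory with the ATP appended (residue name ATP, chain T).
    """
    top = hairpin.trajectory.topology
    frame = hairpin.trajectory.coords[0]
    sel = (top.residue_index == target_residue) & (top.atom_name == target_atom)
    if not sel.any():
        raise ValueError(f"target atom {target_atom} of residue {target_residue} not found")
    a_pos = frame[np.nonzero(sel)[0][0]]

    near = frame[np.linalg.norm(frame - a_pos, axis=1) < 0.6]
    local = near.mean(axis=0)
    u0 = a_pos - local
    if np.linalg.norm(u0) < 1e-9:
        u0 = np.array([1.0, 0.0, 0.0])
    u0 = u0 / np.linalg.norm(u0)

    atoms = _atp_atoms()
    xyz0 = np.array([p for *_, p in atoms])
    names = [n for n, _, _ in atoms]
    i_n6, i_h61 = names.index("N6"), names.index("H61")

    def _place(u, spin_deg):
        """Rigid ATP placement with the H61 bond aimed at the acceptor."""
        xyz = xyz0 - xyz0[i_n6]
        rot = _rotation_between(xyz[i_h61], -u)
        xyz = xyz @ rot.T
        xyz = xyz @ _axis_rotation(u, spin_deg).T        # free spin about the bond
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        xyz = xyz @ _axis_rotation(perp, 180.0 - angle_deg).T   # D-H...A tilt
        return xyz + (a_pos + distance * u)

    # search outward directions and spins for a placement in which the
    # planted bond is the ONLY donor/acceptor pair meeting the criteria;
    # candidate placements are scored with the actual geometric criterion
    from .contacts import ATP_ACCEPTORS, ATP_DONORS, RNA_ACCEPTORS, RNA_DONORS

    target_idx = int(np.nonzero(sel)[0][0])
    target_res = str(top.residue_name[target_idx])
    if target_atom not in RNA_ACCEPTORS[target_res]:
        raise ValueError(f"{target_res}:{target_atom} is not a hydrogen-bond "
                         "acceptor; plant against an acceptor atom")

    local = np.nonzero(np.linalg.norm(frame - a_pos, axis=1) < 2.5)[0]
    by_res: dict = {}
    for i in local:
        by_res.setdefault(int(top.residue_index[i]), {})[str(top.atom_name[i])] = i
    rna_acc, rna_don = [], []
    for resi_l, amap in by_res.items():
        any_i = next(iter(amap.values()))
        res = str(top.residue_name[any_i])
        for name, i in amap.items():
            if i != target_idx and name in RNA_ACCEPTORS[res]:
                rna_acc.append(i)
            if (res, name) in RNA_DONORS:
                hs = [amap[h] for h in RNA_DONORS[(res, name)] if h in amap]
                if hs:
                    rna_don.append((i, hs))
    rna_acc = np.array(rna_acc, dtype=int)

    atp_don = [(names.index(n), [names.index(h) for h in hs if h in names])
               for n, hs in ATP_DONORS.items() if n in names]
    atp_acc = [names.index(n) for n in ATP_ACCEPTORS if n in names]

    def _ang(d, h, a):
        v1, v2 = d - h, a - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    def _stray_bonds(xyz):
        """Criterion-satisfying pairs besides the planted one."""
        n = 0
        for d_i, hs in atp_don:
            targets = np.concatenate([rna_acc, [target_idx]]) if d_i != i_n6 else rna_acc
            dd = np.linalg.norm(frame[targets] - xyz[d_i], axis=1)
            for j in np.nonzero(dd < 0.4)[0]:
                if any(_ang(xyz[d_i], xyz[h], frame[targets[j]]) > 120.0 for h in hs):
                    n += 1
        axyz = xyz[atp_acc]
        for d_i, hs in rna_don:
            dd = np.linalg.norm(axyz - frame[d_i], axis=1)
            for j in np.nonzero(dd < 0.4)[0]:
                if any(_ang(frame[d_i], frame[h], axyz[j]) > 120.0 for h in hs):
                    n += 1
        return n

    golden = np.pi * (3.0 - np.sqrt(5.0))
    best, best_key = None, None
    n_dirs = 100
    for i in range(n_dirs):
        z = 1.0 - 2.0 * (i + 0.5) / n_dirs
        r = np.sqrt(max(1.0 - z * z, 0.0))
        u = np.array([r * np.cos(golden * i), r * np.sin(golden * i), z])
        if np.dot(u, u0) < 0.1:
            continue
        for spin in range(0, 360, 30):
            cand = _place(u, float(spin))
            strays = _stray_bonds(cand)
            margin = float(np.min(np.linalg.norm(
                cand[[d for d, _ in atp_don] + atp_acc][:, None, :]
                - frame[rna_acc][None, :, :], axis=2)))
            key = (strays, -margin)   # fewest strays, then largest clearance
            if best_key is None or key < best_key:
                best, best_key = cand, key
        if best_key is not None and best_key[0] == 0 and -best_key[1] > 0.45:
            break
    xyz = best

    new_top = Topology(
        atom_name=list(top.atom_name) + names,
        residue_name=list(top.residue_name) + ["ATP"] * len(names),
        residue_index=list(top.residue_index) + [int(top.residue_index.max()) + 1] * len(names),
        chain_id=list(top.chain_id) + ["T"] * len(names),
        element=list(top.element) + [e for _, e, _ in atoms],
    )
    coords = np.concatenate([frame, xyz])[None, :, :]
    return Trajectory(topology=new_top, coords=coords,
                      frame_time=hairpin.trajectory.frame_time)


def gen_atp_binding_trajectory(hairpin: HairpinModel, target_residue: int,
                               target_atom: str, n_frames: int,
                               bound_fraction: float, seed: int = 0,
                               jitter: float = 0.0) -> Trajectory:
    """Toy trajectory where ATP is bound in a set fraction of frames.

    Bound frames use the planted hydrogen-bond geometry; unbound frames
    displace the ATP 3 nm outward.  With ``jitter`` > 0 all atoms get
    Gaussian positional noise (nm) — useful for oracle fixtures, not for
    preserving the planted contact.  Mean per-frame bond counts at the
    target's moiety equal ``round(bound_fraction*n_frames)/n_frames``.
    """
    base = plant_atp(hairpin, target_residue, target_atom)
    rng = np.random.default_rng(seed)
    n_bound = int(round(bound_fraction * n_frames))
    n_rna = hairpin.trajectory.topology.n_atoms
    atp_xyz = base.coords[0, n_rna:]
    away = atp_xyz.mean(axis=0) - base.coords[0, :n_rna].mean(axis=0)
    away = 3.0 * away / np.linalg.norm(away)

    frames = np.repeat(base.coords, n_frames, axis=0)
    for f in range(n_bound, n_frames):
        frames[f, n_rna:] += away
    if jitter > 0:
        frames = frames + rng.normal(0.0, jitter, frames.shape)
    return Trajectory(topology=base.topology, coords=frames,
                      frame_time=base.frame_time)


# --- grouped measurements ------------------------------------------------

def gen_groups(means, sds, ns, seed: int = 0) -> list:
    """Independent Gaussian samples per group (equal-length parameter lists)."""
    means, sds, ns = list(means), list(sds), list(ns)
    if not len(means) == len(sds) == len(ns):
        raise ValueError("means, sds, ns must have equal lengths")
    if any(n < 2 for n in ns):
        raise ValueError("every group needs n >= 2")
    rng = np.random.default_rng(seed)
    return [rng.normal(m, s, size=n) for m, s, n in zip(means, sds, ns)]


def load_lm4u_star() -> dict:
    """Pairing table of the lm4U* thermometer hairpin control (14 bp).

    This is a synthetic stand-in secondary structure: the real hairpin
    follows no repeat rule, and only its canonical pair count (14) is
    anchored; the register here is illustrative.
    """
    import json
    from importlib import resources

    with resources.files("cagrna.data").joinpath(
            "lm4u_star_pairs_synthetic.json").open() as fh:
        return json.load(fh)
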