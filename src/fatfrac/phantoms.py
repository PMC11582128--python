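"""Digital phantoms and simulated multi-echo acquisitions.

Two phantom geometries are provided:

* a vial phantom — six circular vials of oil/agarose emulsion with known
  volume fat fractions (VFF 5–100 %) arranged in a ring inside a
  water-filled disk, the standard object for validating PDFF accuracy;
* a calf-like phantom — low-PDFF muscle surrounded by a high-PDFF
  subcutaneous fat ring, with a tibia (near-zero signal) enclosing
  high-PDFF marrow, and ANT/SOL/GM muscle sectors usable as ROIs.

Ground-truth VFF is used directly as the PDFF truth map (proton-density
differences between oil and gel are ignored, as in direct VFF-vs-PDFF
agreement analyses). On top of the anatomy the generator can impose a
smooth-plus-local B0 inhomogeneity, echo-dependent eddy-current phase
ramps along the readout direction, and i.i.d. circular complex Gaussian
noise. Chemical-shift displacement and k-space effects are deliberately
not simulated; phase errors are imposed in image space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal import AcquisitionProtocol, FatSpectrumModel, fat_phasor

__all__ = [
    "DigitalPhantom",
    "EchoSeries",
    "make_vial_phantom",
    "make_calf_phantom",
    "make_field_map",
    "apply_eddy_phase",
    "simulate_acquisition",
]

LABEL_BACKGROUND = 0


@dataclass
class DigitalPhantom:
    """Voxelwise ground truth for a simulated object.

    ``pdff_truth`` in [0, 1]; ``rho_total`` in arbitrary units (0 in
    background); ``r2s_truth`` and ``b0_truth`` in Hz; ``phi0_truth`` in
    radians; ``labels`` an integer region map with names in
    ``label_names``.
    """

    pdff_truth: np.ndarray
    rho_total: np.ndarray
    r2s_truth: np.ndarray
    b0_truth: np.ndarray
    phi0_truth: np.ndarray
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        shape = self.pdff_truth.shape
        for name in ("rho_total", "r2s_truth", "b0_truth", "phi0_truth", "labels"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape mismatch with pdff_truth {shape}")
        if np.any(self.pdff_truth < 0) or np.any(self.pdff_truth > 1):
            raise ValueError("pdff_truth must lie in [0, 1]")
        if np.any(self.rho_total < 0):
            raise ValueError("rho_total must be non-negative")
        for lab in self.label_names:
            if lab != LABEL_BACKGROUND and np.count_nonzero(self.labels == lab) == 0:
                raise ValueError(f"label {lab} ({self.label_names[lab]}) has no voxels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pdff_truth.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the region with the given label name."""
        for lab, nm in self.label_names.items():
            if nm == name:
                return self.labels == lab
        raise KeyError(f"no region named {name!r}")

    @property
    def foreground(self) -> np.ndarray:
        return self.rho_total > 0


@dataclass
class EchoSeries:
    """Complex multi-echo image stack, echo axis first.

    ``data`` has shape ``(n_echoes, ny, nx)`` (or with a leading echo axis
    over any spatial shape); image axis ``"y"`` is ``data`` axis -2 and
    ``"x"`` is axis -1, matching ``AcquisitionProtocol`` axis labels.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    noise_sd: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.shape[0] != self.protocol.n_echoes:
            raise ValueError(
                f"echo axis {self.data.shape[0]} != protocol n_echoes {self.protocol.n_echoes}"
            )
        if not np.iscomplexobj(self.data):
            raise ValueError("data must be complex")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def axis_index(self, axis_label: str) -> int:
        """Map an image-axis label ('x'/'y') to a ``data`` array axis."""
        mapping = {"y": self.data.ndim - 2, "x": self.data.ndim - 1}
        if axis_label not in mapping:
            raise KeyError(f"unknown axis label {axis_label!r}")
        return mapping[axis_label]


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_vial_phantom(
    vff_list=(0.05, 0.10, 0.25, 0.50, 0.75, 1.00),
    grid_size: int = 128,
    disk_radius_frac: float = 0.46,
    ring_radius_frac: float = 0.28,
    vial_radius_frac: float = 0.11,
    r2s: float = 50.0,
    bath_r2s: float = 30.0,
) -> DigitalPhantom:
    """Ring of oil-emulsion vials inside a water disk.

    The default VFFs (5, 10, 25, 50, 75, 100 %) are used directly as the
    PDFF ground truth of each vial; the surrounding bath is pure water.
    Radii are fractions of the grid size. Fails if the requested geometry
    would overlap vials.
    """
    vff = np.asarray(vff_list, dtype=float)
    if vff.size == 0:
        raise ValueError("vff_list must be non-empty")
    if np.any(vff < 0) or np.any(vff > 1):
        raise ValueError("VFFs must lie in [0, 1]")
    shape = (grid_size, grid_size)
    center = ((grid_size - 1) / 2.0, (grid_size - 1) / 2.0)
    R_ring = ring_radius_frac * grid_size
    r_vial = vial_radius_frac * grid_size
    n = vff.size
    if n > 1:
        min_sep = 2 * R_ring * np.sin(np.pi / n)
        if min_sep < 2 * r_vial:
            raise ValueError(
                f"vials of radius {r_vial:.1f} px overlap at ring radius {R_ring:.1f} px "
                f"for {n} vials; enlarge the grid or shrink the vials"
            )
    if R_ring + r_vial > disk_radius_frac * grid_size:
        raise ValueError("vial ring does not fit inside the water disk")

    labels = np.zeros(shape, dtype=int)
    label_names = {LABEL_BACKGROUND: "background", 1: "bath"}
    bath = _disk(shape, center, disk_radius_frac * grid_size)
    labels[bath] = 1
    pdff = np.zeros(shape)
    for k, f in enumerate(vff):
        ang = 2 * np.pi * k / n - np.pi / 2
        cy = center[0] + R_ring * np.sin(ang)
        cx = center[1] + R_ring * np.cos(ang)
        m = _disk(shape, (cy, cx), r_vial)
        lab = 2 + k
        labels[m] = lab
        label_names[lab] = f"vial-{k + 1}"
        pdff[m] = f

    rho = np.where(labels > 0, 1.0, 0.0)
    r2s_map = np.where(labels >= 2, r2s, np.where(labels == 1, bath_r2s, 0.0))
    zeros = np.zeros(shape)
    return DigitalPhantom(pdff, rho, r2s_map, zeros.copy(), zeros.copy(), labels, label_names)


def make_calf_phantom(
    grid_size: int = 128,
    muscle_pdff: float = 0.03,
    fat_ring_pdff: float = 0.90,
    marrow_pdff: float = 0.90,
    muscle_r2s: float = 40.0,
    fat_r2s: float = 60.0,
    bone_rho: float = 0.02,
) -> DigitalPhantom:
    """Calf-like slice: muscle sectors, subcutaneous fat ring, tibia + marrow.

    The muscle disk is split into three angular sectors emulating the
    anterior compartment (ANT), soleus (SOL) and gastrocnemius medialis
    (GM) ROIs. The tibia is modelled as a low-signal ring (cortical bone,
    ``bone_rho`` of the soft-tissue magnitude) around high-PDFF marrow, so
    that bone behaves as the low-SNR region that gets masked during field
    mapping.
    """
    for val, nm in ((muscle_pdff, "muscle_pdff"), (fat_ring_pdff, "fat_ring_pdff"),
                    (marrow_pdff, "marrow_pdff")):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{nm} must lie in [0, 1]")
    shape = (grid_size, grid_size)
    c = ((grid_size - 1) / 2.0, (grid_size - 1) / 2.0)
    outer = _disk(shape, c, 0.46 * grid_size)
    inner = _disk(shape, c, 0.38 * grid_size)
    fat_ring = outer & ~inner

    # tibia anterior-left of center, marrow inside cortical shell
    tib_c = (c[0] - 0.16 * grid_size, c[1] - 0.14 * grid_size)
    bone_outer = _disk(shape, tib_c, 0.10 * grid_size)
    marrow = _disk(shape, tib_c, 0.06 * grid_size)
    bone = bone_outer & ~marrow
    muscle = inner & ~bone_outer

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ang = np.arctan2(yy - c[0], xx - c[1])  # y grows "posterior"
    ant = muscle & (ang < -np.pi / 4) & (ang >= -3 * np.pi / 4)
    sol = muscle & (ang >= np.pi / 4) & (ang < 3 * np.pi / 4)
    gm = muscle & ~ant & ~sol

    labels = np.zeros(shape, dtype=int)
    labels[gm] = 3
    labels[ant] = 1
    labels[sol] = 2
    labels[fat_ring] = 4
    labels[bone] = 5
    labels[marrow] = 6
    label_names = {0: "background", 1: "ANT", 2: "SOL", 3: "GM",
                   4: "subcutaneous_fat", 5: "bone", 6: "marrow"}

    pdff = np.zeros(shape)
    pdff[muscle] = muscle_pdff
    pdff[fat_ring] = fat_ring_pdff
    pdff[marrow] = marrow_pdff
    rho = np.zeros(shape)
    rho[outer] = 1.0
    rho[bone] = bone_rho
    r2s = np.zeros(shape)
    r2s[muscle] = muscle_r2s
    r2s[fat_ring] = fat_r2s
    r2s[marrow] = fat_r2s
    r2s[bone] = 200.0
    zeros = np.zeros(shape)
    return DigitalPhantom(pdff, rho, r2s, zeros.copy(), zeros.copy(), labels, label_names)


def make_field_map(
    phantom: DigitalPhantom,
    smooth_amplitude: float = 0.0,
    local_gradient_amplitude: float = 0.0,
    n_perturbations: int = 4,
    local_width_frac: float = 0.06,
    susceptibility_offset: float = 0.0,
    seed: int = 0,
) -> DigitalPhantom:
    """Add a smooth-plus-local B0 inhomogeneity to a phantom (returns a copy).

    The smooth term is a low-order 2-D polynomial scaled so its absolute
    maximum over the phantom foreground equals ``smooth_amplitude`` (Hz).
    The local term places dipole-like lobes (r^-2-decaying,
    sign-alternating) at points on fat/bone interfaces, scaled to peak
    amplitude ``local_gradient_amplitude``. ``susceptibility_offset``
    (Hz) adds a sharp step field shift *inside* fat-like tissue (fat ring,
    marrow, bone, oil vials) — the bulk susceptibility difference of fatty
    tissue that creates the abrupt field discontinuities driving fat-water
    swaps: once the step exceeds half the fat-water beat frequency, the
    spatial smoothness term itself favors the swap-aliased field valley. Deterministic given
    ``seed``. All amplitudes are in Hz, so callers model the linear growth
    of inhomogeneity with field strength by scaling them with B0.
    """
    ny, nx = phantom.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    u = (xx - (nx - 1) / 2) / (nx / 2)
    v = (yy - (ny - 1) / 2) / (ny / 2)
    smooth = 0.8 * u + 0.5 * v + 0.6 * u * v + 0.4 * (u**2 - 0.5) - 0.3 * v**2
    # amplitudes refer to the object: normalize over foreground voxels
    norm_region = phantom.foreground if np.any(phantom.foreground) else np.ones_like(smooth, bool)
    peak = np.max(np.abs(smooth[norm_region]))
    b0 = smooth_amplitude * smooth / peak if smooth_amplitude else np.zeros_like(smooth)

    if local_gradient_amplitude:
        rng = np.random.default_rng(seed)
        interface = _interface_voxels(phantom.labels, phantom.label_names)
        if interface[0].size:
            idx = rng.choice(interface[0].size, size=min(n_perturbations, interface[0].size),
                             replace=False)
            local = np.zeros_like(smooth)
            for sgn, i in zip(np.resize([1.0, -1.0], idx.size), idx):
                cy, cx = interface[0][i], interface[1][i]
                r2 = (yy - cy) ** 2 + (xx - cx) ** 2
                width = (local_width_frac * max(ny, nx)) ** 2
                local += sgn * width / (r2 + width)
            local *= local_gradient_amplitude / max(np.max(np.abs(local)), 1e-12)
            b0 = b0 + local

    if susceptibility_offset:
        # sharp at voxel scale, as bulk-susceptibility boundaries are
        step = _fatlike_mask(phantom.labels, phantom.label_names).astype(float)
        b0 = b0 + susceptibility_offset * step

    return replace(phantom, b0_truth=b0)


def _fatlike_mask(labels: np.ndarray, label_names: dict) -> np.ndarray:
    """Fat, marrow, bone and oil-vial regions (the susceptibility sources)."""
    keywords = ("fat", "marrow", "bone", "vial")
    labs = [lab for lab, nm in label_names.items()
            if any(k in nm.lower() for k in keywords)]
    return np.isin(labels, labs)


def _interface_voxels(labels: np.ndarray, label_names: dict):
    """Voxels on the boundary of high-susceptibility-contrast regions."""
    fatlike = _fatlike_mask(labels, label_names)
    edge = np.zeros_like(fatlike)
    edge[:-1, :] |= fatlike[:-1, :] != fatlike[1:, :]
    edge[:, :-1] |= fatlike[:, :-1] != fatlike[:, 1:]
    return np.nonzero(edge)


def simulate_acquisition(
    phantom: DigitalPhantom,
    model: FatSpectrumModel,
    protocol: AcquisitionProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EchoSeries:
    """Forward-simulate the multi-echo acquisition of a phantom.

    Applies the voxelwise GRE signal model to the phantom truth maps (water
    and fat share the initial phase ``phi0_truth``) and adds i.i.d.
    circular complex Gaussian noise of complex standard deviation
    ``noise_sd`` (per-channel SD ``noise_sd / sqrt(2)``). With
    ``rho_total = 1`` in the object, SNR is ``1 / noise_sd``.
    Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    te = protocol.te_array
    c = np.asarray(fat_phasor(model, protocol.b0, te))  # (n,)
    w = phantom.rho_total * (1.0 - phantom.pdff_truth) * np.exp(1j * phantom.phi0_truth)
    f = phantom.rho_total * phantom.pdff_truth * np.exp(1j * phantom.phi0_truth)
    env = np.exp(
        (2j * np.pi * phantom.b0_truth[None] - phantom.r2s_truth[None])
        * te[:, None, None]
    )
    data = (w[None] + f[None] * c[:, None, None]) * env
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma_ch = noise_sd / np.sqrt(2.0)
        data = data + rng.normal(scale=sigma_ch, size=data.shape) + 1j * rng.normal(
            scale=sigma_ch, size=data.shape
        )
    prov = {"generator": "simulate_acquisition", "seed": seed, "noise_sd": noise_sd,
            "fat_model": model.name, "protocol": protocol.name or "custom",
            "te_ms": (te * 1e3).tolist(), "b0": protocol.b0}
    return EchoSeries(data=data, protocol=protocol, noise_sd=noise_sd, provenance=prov)


def apply_eddy_phase(
    series: EchoSeries,
    first_echo_phase: float = 0.0,
    readout_gradient: float = 0.0,
    mode: str = "first-echo-only",
    echo_decay: float = 0.5,
) -> EchoSeries:
    """Impose eddy-current-like phase ramps along the readout direction.

    The ramp at readout coordinate ``x`` (voxels, centered) is
    ``first_echo_phase + readout_gradient * x`` radians. Modes:

    ``"first-echo-only"``
        only echo 1 is perturbed — the error a magnitude-first-echo mixed
        fit is designed to absorb;
    ``"all-echoes-linear"``
        every echo n gets the same spatially linear ramp scaled by
        ``echo_decay**(n-1)``, mimicking eddy currents that decay over the
        echo train. Because the scaling is not linear in TE, the error
        cannot be absorbed into the field map and persists after a
        first-echo-magnitude fit.

    Returns a new series; applying the negated ramp restores the input
    bit-exactly.
    """
    if mode not in ("first-echo-only", "all-echoes-linear"):
        raise ValueError(f"unknown mode {mode!r}")
    axis = series.axis_index(series.protocol.readout_axis)
    n_read = series.data.shape[axis]
    coord = np.arange(n_read) - (n_read - 1) / 2.0
    ramp = first_echo_phase + readout_gradient * coord
    shape = [1] * series.data.ndim
    shape[axis] = n_read
    ramp = ramp.reshape(shape[1:])  # spatial broadcast shape

    data = series.data.copy()
    if mode == "first-echo-only":
        data[0] = data[0] * np.exp(1j * ramp)
    else:
        for n in range(data.shape[0]):
            data[n] = data[n] * np.exp(1j * ramp * echo_decay**n)
    prov = dict(series.provenance)
    prov.setdefault("eddy", [])
    prov["eddy"] = list(prov["eddy"]) + [
        {"mode": mode, "first_echo_phase": first_echo_phase,
         "readout_gradient": readout_gradient, "echo_decay": echo_decay}
    ]
    return EchoSeries(data=data, protocol=series.protocol,
                      noise_sd=series.noise_sd, provenance=prov)
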