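"""Synthetic multi-domain, multi-sequence 3D brain phantoms.

Every downstream stage of the package (preprocessing, the hybrid encoder,
domain adaptation, the robustness harness) is exercised on these phantoms,
so no external imaging data is required.  A phantom is a 4-channel volume
(T1, T1ce, T2, FLAIR) containing a nested ellipsoidal tumor — necrotic
core, enhancing rim, surrounding edema — placed on a smooth brain-like
background.  Two "domains" emulate acquisition sites that differ in tissue
contrast, multiplicative bias field, noise level, and nominal voxel
spacing.  Graded perturbation operators and scanner profiles support the
robustness protocol.

Determinism: every operation is a pure function of its inputs and an
explicit integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

SEQUENCES = ("t1", "t1ce", "t2", "flair")

#: per-sequence mean intensity for (brain, edema, necrotic core, enhancing rim).
#: Ordering mimics clinical appearance: enhancing rim brightest on T1ce,
#: edema brightest on FLAIR, core dark on T1/T1ce.
DEFAULT_INTENSITY_TABLE: dict[str, tuple[float, float, float, float]] = {
    "t1": (1.00, 0.70, 0.40, 0.85),
    "t1ce": (1.00, 0.70, 0.30, 1.60),
    "t2": (1.00, 1.50, 1.20, 1.10),
    "flair": (1.00, 1.70, 0.90, 1.20),
}

# region-mask codes
BG, EDEMA, CORE, ENHANCING = 0, 1, 2, 3


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry / intensity recipe for one phantom cohort."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radii: tuple[float, float, float] = (3.0, 5.0, 8.0)  # core < rim < edema (voxels)
    class_count: int = 2
    intensity_table: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_TABLE))
    noise_sigma: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        core, rim, edema = self.tumor_radii
        if edema > 0 and not (core < rim < edema):
            raise InvalidSpecError("tumor radii must satisfy core < rim < edema")
        if any(2 * edema >= s for s in self.grid_shape):
            raise InvalidSpecError("edema radius does not fit inside the grid")
        if self.class_count < 2:
            raise InvalidSpecError("class_count must be >= 2")
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.spacing):
            raise InvalidSpecError("grid_shape and spacing must be positive")


@dataclass(frozen=True)
class DomainStyle:
    """Acquisition style of one domain (0 = source, 1 = target)."""

    domain_id: int
    contrast_gain: float = 1.0
    bias_field_amplitude: float = 0.0
    bias_field_smoothness: float = 8.0  # mm
    noise_sigma: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.domain_id not in (0, 1):
            raise InvalidSpecError("domain_id must be 0 (source) or 1 (target)")


#: severity triples (low, medium, high) for each perturbation family
SEVERITY_PARAMS: dict[str, dict[str, float]] = {
    "intensity_scaling": {"zero": 1.0, "low": 0.95, "medium": 0.90, "high": 0.80},
    "gaussian_noise": {"zero": 0.0, "low": 0.05, "medium": 0.10, "high": 0.20},
    "elastic_deformation": {"zero": 0.0, "low": 1.0, "medium": 2.0, "high": 4.0},
    "motion_blur": {"zero": 1.0, "low": 2.0, "medium": 3.0, "high": 5.0},
}

SEVERITIES = ("low", "medium", "high")


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    severity: str = "low"

    def __post_init__(self):
        if self.kind not in SEVERITY_PARAMS:
            raise InvalidSpecError(f"unknown perturbation kind: {self.kind!r}")
        if self.severity not in SEVERITY_PARAMS[self.kind]:
            raise InvalidSpecError(f"unknown severity: {self.severity!r}")

    @property
    def param(self) -> float:
        return SEVERITY_PARAMS[self.kind][self.severity]


SCANNER_PROFILES = ("identity", "low_field", "bias_field", "coil_scaling",
                    "high_noise_low_contrast")


@dataclass(frozen=True)
class ScannerProfile:
    """Parameterized rendering of dataset-level scanner characteristics."""

    profile_id: str
    snr_factor: float = 3.0        # low_field: output noise std = in-mask std / snr_factor
    bias_amplitude: float = 0.4    # bias_field: sequence-wise log-field amplitude
    coil_gain_scale: float = 0.3   # coil_scaling: amplitude of the smooth gain map
    noise_factor: float = 2.0      # high_noise_low_contrast
    contrast_factor: float = 0.6   # high_noise_low_contrast

    def __post_init__(self):
        if self.profile_id not in SCANNER_PROFILES:
            raise InvalidSpecError(f"unknown scanner profile: {self.profile_id!r}")


@dataclass
class LabeledVolume:
    """A rendered (or domain-free) phantom with its ground truth."""

    channels: dict[str, np.ndarray]         # sequence -> (X,Y,Z) float array
    brain_mask: np.ndarray                  # (X,Y,Z) uint8
    region_mask: np.ndarray                 # (X,Y,Z) uint8, codes BG/EDEMA/CORE/ENHANCING
    spacing: tuple[float, float, float]
    class_label: int
    anatomy_seed: int
    domain_id: int | None = None            # None for domain-free anatomy

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(
            channels={k: v.copy() for k, v in self.channels.items()},
            brain_mask=self.brain_mask.copy(),
            region_mask=self.region_mask.copy(),
            spacing=tuple(self.spacing),
            class_label=self.class_label,
            anatomy_seed=self.anatomy_seed,
            domain_id=self.domain_id,
        )

    def stacked(self) -> np.ndarray:
        """(4, X, Y, Z) array in the canonical T1, T1ce, T2, FLAIR order."""
        return np.stack([self.channels[s] for s in SEQUENCES])


# --------------------------------------------------------------------- anatomy
def _ellipsoid_distance(shape, center, radii, axes_scale):
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum(((g - c) / (r * a)) ** 2
             for g, c, r, a in zip(grids, center, [radii] * 3, axes_scale))
    return np.sqrt(d2)


def generate_anatomy(spec: PhantomSpec, anatomy_seed: int) -> LabeledVolume:
    """Generate the domain-free "true tissue" phantom.

    The class label is drawn uniformly from ``spec.class_count`` and the
    tumor geometry is then conditioned on it — higher classes get a
    thicker enhancing rim (a larger enhancement fraction), so grading is
    learnable from the image alone.  Deterministic given (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(anatomy_seed)]))
    shape = tuple(spec.grid_shape)
    core_r, rim_r, edema_r = spec.tumor_radii

    # brain: one big smooth ellipsoid filling most of the grid
    center = np.array(shape) / 2.0
    brain_axes = np.array([0.44, 0.40, 0.42]) * np.array(shape)
    d_brain = _ellipsoid_distance(shape, center, 1.0, brain_axes)
    brain_mask = (d_brain <= 1.0).astype(np.uint8)

    # smooth background variation shared across sequences
    bgnoise = rng.normal(size=shape)
    background = 1.0 + 0.08 * _smooth_unit_field(bgnoise, sigma=max(shape) / 6.0)

    region = np.zeros(shape, dtype=np.uint8)
    class_label = 0
    if edema_r > 0:
        class_label = int(rng.integers(spec.class_count))
        # rim thickness encodes the grade analog: higher classes get a
        # thicker enhancing shell (larger enhancement fraction)
        frac = (class_label + 1) / (spec.class_count + 1)  # in (0,1)
        jitter = rng.uniform(0.95, 1.05, size=4)
        core_eff = max(core_r * jitter[0], 0.8)
        thickness = (rim_r - core_r) * 2.0 * frac * jitter[1]
        rim_eff = core_eff + max(thickness, 0.15)
        edema_eff = max(edema_r * jitter[2], rim_eff + 0.5)
        axes = rng.uniform(0.85, 1.15, size=3)
        axes /= axes.prod() ** (1 / 3)
        margin = edema_eff * np.max(axes) + 2
        lo = np.maximum(margin, center - 0.25 * np.array(shape))
        hi = np.minimum(np.array(shape) - margin, center + 0.25 * np.array(shape))
        tumor_center = np.array([rng.uniform(l, h) if h > l else c
                                 for l, h, c in zip(lo, hi, center)])
        r_norm = _ellipsoid_distance(shape, tumor_center, 1.0, axes)
        region[(r_norm <= edema_eff)] = EDEMA
        region[(r_norm <= rim_eff)] = ENHANCING
        region[(r_norm <= core_eff)] = CORE
        region[brain_mask == 0] = BG

    # paint per-sequence intensities
    channels: dict[str, np.ndarray] = {}
    for seq in SEQUENCES:
        brain_i, edema_i, core_i, enh_i = spec.intensity_table[seq]
        vol = background * brain_i
        vol[region == EDEMA] = edema_i
        vol[region == CORE] = core_i
        vol[region == ENHANCING] = enh_i
        vol *= brain_mask
        # soft tissue interfaces
        vol = ndimage.gaussian_filter(vol, sigma=0.7)
        vol *= brain_mask
        channels[seq] = vol

    return LabeledVolume(
        channels=channels,
        brain_mask=brain_mask,
        region_mask=region,
        spacing=tuple(spec.spacing),
        class_label=class_label,
        anatomy_seed=int(anatomy_seed),
        domain_id=None,
    )


def _smooth_unit_field(white: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit max-abs."""
    f = ndimage.gaussian_filter(white, sigma=sigma)
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


def make_bias_field(shape, amplitude: float, smoothness_mm: float,
                    spacing, rng: np.random.Generator) -> np.ndarray:
    """Smooth, positive, multiplicative field: exp of smoothed white noise.

    `amplitude` is the maximum |log b| so the field lies in
    [exp(-a), exp(+a)]; `smoothness_mm` sets the Gaussian kernel width.
    """
    if amplitude == 0:
        return np.ones(shape)
    sigma_vox = [smoothness_mm / s for s in spacing]
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma_vox)
    m = np.max(np.abs(f))
    if m > 0:
        f = f / m
    return np.exp(amplitude * f)


# --------------------------------------------------------------------- render
def render_domain(anatomy: LabeledVolume, style: DomainStyle,
                  render_seed: int, return_field: bool = False):
    """Render a domain-free anatomy under an acquisition style.

    Observed intensity follows the multiplicative acquisition model
    ``v = b * t_c + eps`` with ``b`` a smooth positive bias field and
    ``eps`` Gaussian noise.  ``t_c`` is the true tissue signal with its
    inter-tissue contrast compressed about the in-brain mean by
    ``contrast_gain`` (a pure global gain would be removed exactly by
    z-score normalization and carry no domain information).  Labels and
    region masks are untouched; the same anatomy rendered under both
    styles forms a cross-domain positive pair.
    """
    if anatomy.domain_id is not None:
        raise ValueError("render_domain expects a domain-free anatomy")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(render_seed), style.domain_id, anatomy.anatomy_seed]))
    out = anatomy.copy()
    out.domain_id = style.domain_id
    out.spacing = tuple(style.spacing)
    mask = anatomy.brain_mask.astype(bool)
    fields = {}
    for seq in SEQUENCES:
        t = anatomy.channels[seq]
        if style.contrast_gain == 1.0:
            t_c = t  # exact identity path
        else:
            m = t[mask].mean() if mask.any() else 0.0
            t_c = np.where(mask, m + style.contrast_gain * (t - m), t)
        b = make_bias_field(t.shape, style.bias_field_amplitude,
                            style.bias_field_smoothness, style.spacing, rng)
        v = b * t_c
        if style.noise_sigma > 0:
            v = v + rng.normal(0.0, style.noise_sigma, size=t.shape)
        v *= anatomy.brain_mask
        out.channels[seq] = v
        fields[seq] = b
    if return_field:
        return out, fields
    return out


# --------------------------------------------------------------- perturbation
def apply_perturbation(vol: LabeledVolume, pert: PerturbationSpec,
                       seed: int) -> LabeledVolume:
    """Apply one graded input perturbation; class labels never change.

    Only elastic deformation touches the region mask, and it warps image
    and mask with the same displacement field.
    """
    kind_index = list(SEVERITY_PARAMS).index(pert.kind)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), kind_index]))
    out = vol.copy()
    p = pert.param
    mask = vol.brain_mask.astype(bool)

    if pert.kind == "intensity_scaling":
        for seq in SEQUENCES:
            out.channels[seq] = vol.channels[seq] * p
    elif pert.kind == "gaussian_noise":
        ref = np.std(np.concatenate([vol.channels[s][mask] for s in SEQUENCES])) if mask.any() else 1.0
        sigma = p * ref
        for seq in SEQUENCES:
            noise = rng.normal(0.0, 1.0, size=vol.channels[seq].shape)
            out.channels[seq] = vol.channels[seq] + sigma * noise
    elif pert.kind == "elastic_deformation":
        if p > 0:
            disp = _elastic_displacement(vol.brain_mask.shape, max_disp=p, rng=rng)
            for seq in SEQUENCES:
                out.channels[seq] = _warp(vol.channels[seq], disp, order=1)
            out.brain_mask = _warp(vol.brain_mask, disp, order=0).astype(np.uint8)
            out.region_mask = _warp(vol.region_mask, disp, order=0).astype(np.uint8)
    elif pert.kind == "motion_blur":
        L = int(round(p))
        if L > 1:
            axis = int(rng.integers(3))
            kernel = np.ones(L) / L
            for seq in SEQUENCES:
                out.channels[seq] = ndimage.convolve1d(
                    vol.channels[seq], kernel, axis=axis, mode="nearest")
    return out


def _elastic_displacement(shape, max_disp: float, rng, smooth_sigma: float = 4.0):
    disp = []
    for _ in range(3):
        f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=smooth_sigma)
        m = np.max(np.abs(f))
        disp.append(max_disp * f / m if m > 0 else f)
    return disp


def _warp(vol: np.ndarray, disp, order: int) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in vol.shape], indexing="ij")
    sample = [c + d for c, d in zip(coords, disp)]
    return ndimage.map_coordinates(vol.astype(float), sample, order=order, mode="nearest")


# -------------------------------------------------------------- scanner shift
def apply_scanner_profile(vol: LabeledVolume, profile: ScannerProfile,
                          seed: int) -> LabeledVolume:
    """Re-render a volume as if acquired on a different scanner.

    Grid shape, brain mask and all labels are preserved.  Profiles:

    - ``low_field``: slight smoothing plus added noise scaled so SNR drops
      by roughly ``snr_factor``.
    - ``bias_field``: strong sequence-wise multiplicative non-uniformity.
    - ``coil_scaling``: smooth per-coil gain map (linear ramp + smooth
      random component) of amplitude ``coil_gain_scale``; scale 0 is the
      identity.
    - ``high_noise_low_contrast``: shrinks inter-tissue intensity gaps
      about the in-brain mean and raises the noise floor.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed), SCANNER_PROFILES.index(profile.profile_id)]))
    out = vol.copy()
    mask = vol.brain_mask.astype(bool)
    if profile.profile_id == "identity":
        return out
    if profile.profile_id == "low_field":
        for seq in SEQUENCES:
            v = ndimage.gaussian_filter(vol.channels[seq], sigma=0.6)
            sigma = (np.std(vol.channels[seq][mask]) / profile.snr_factor) if mask.any() else 0.0
            v = v + rng.normal(0.0, sigma, size=v.shape)
            out.channels[seq] = v * vol.brain_mask
    elif profile.profile_id == "bias_field":
        for seq in SEQUENCES:  # sequence-wise independent fields
            b = make_bias_field(vol.brain_mask.shape, profile.bias_amplitude,
                                10.0, vol.spacing, rng)
            out.channels[seq] = vol.channels[seq] * b
    elif profile.profile_id == "coil_scaling":
        if profile.coil_gain_scale != 0:
            shape = vol.brain_mask.shape
            ramp = np.linspace(-1, 1, shape[0])[:, None, None] * np.ones(shape)
            smooth = _smooth_unit_field(rng.normal(size=shape), sigma=max(shape) / 4.0)
            gain = 1.0 + profile.coil_gain_scale * 0.5 * (ramp + smooth)
            for seq in SEQUENCES:
                out.channels[seq] = vol.channels[seq] * gain
    elif profile.profile_id == "high_noise_low_contrast":
        for seq in SEQUENCES:
            v = vol.channels[seq]
            m = v[mask].mean() if mask.any() else 0.0
            sigma = (np.std(v[mask]) * (profile.noise_factor - 1.0) / profile.noise_factor
                     if mask.any() else 0.0)
            shrunk = np.where(mask, m + profile.contrast_factor * (v - m), v)
            out.channels[seq] = (shrunk + rng.normal(0.0, sigma, size=v.shape)) * vol.brain_mask
    return out


# ------------------------------------------------------------------- datasets
@dataclass
class PhantomDataset:
    """2·n_per_domain rendered volumes plus the cross-domain pairing table."""

    volumes: list[LabeledVolume]
    pairs: list[dict]  # {"pair_id", "anatomy_seed", "source_index", "target_index", "class"}

    def by_domain(self, domain_id: int) -> list[LabeledVolume]:
        return [v for v in self.volumes if v.domain_id == domain_id]


def build_dataset(spec: PhantomSpec, styles: tuple[DomainStyle, DomainStyle],
                  n_per_domain: int, seed: int,
                  out_dir: str | Path | None = None) -> PhantomDataset:
    """Render `n_per_domain` anatomies under both styles.

    Each anatomy appears once per domain, giving `n_per_domain`
    cross-domain positive pairs with disjoint anatomy seeds.  When
    `out_dir` is given, volumes are written as NIfTI alongside a JSON
    manifest (see :func:`write_dataset`).
    """
    if n_per_domain < 1:
        raise InvalidSpecError("n_per_domain must be >= 1")
    s0, s1 = styles
    if {s0.domain_id, s1.domain_id} != {0, 1}:
        raise InvalidSpecError("styles must cover domain ids 0 and 1")
    if s1.domain_id == 0:
        s0, s1 = s1, s0
    rng = np.random.default_rng(int(seed))
    anatomy_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_per_domain)]
    volumes: list[LabeledVolume] = []
    pairs: list[dict] = []
    for pid, aseed in enumerate(anatomy_seeds):
        anatomy = generate_anatomy(spec, aseed)
        v0 = render_domain(anatomy, s0, render_seed=seed)
        v1 = render_domain(anatomy, s1, render_seed=seed)
        pairs.append({"pair_id": pid, "anatomy_seed": aseed,
                      "source_index": len(volumes), "target_index": len(volumes) + 1,
                      "class": anatomy.class_label})
        volumes.extend([v0, v1])
    ds = PhantomDataset(volumes=volumes, pairs=pairs)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


# ---------------------------------------------------------------------- I/O
def _nifti_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_dataset(ds: PhantomDataset, out_dir: str | Path) -> Path:
    """Write volumes as per-channel NIfTI-1 files plus a JSON manifest."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"volumes": [], "pairs": ds.pairs}
    for i, vol in enumerate(ds.volumes):
        aff = _nifti_affine(vol.spacing)
        stem = f"vol{i:04d}"
        files = {}
        for seq in SEQUENCES:
            p = out_dir / f"{stem}_{seq}.nii.gz"
            nib.save(nib.Nifti1Image(vol.channels[seq].astype(np.float32), aff), p)
            files[seq] = p.name
        for name, arr in (("mask", vol.brain_mask), ("regions", vol.region_mask)):
            p = out_dir / f"{stem}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr.astype(np.uint8), aff), p)
            files[name] = p.name
        manifest["volumes"].append({
            "id": stem, "domain": vol.domain_id, "class": vol.class_label,
            "anatomy_seed": vol.anatomy_seed, "spacing": list(vol.spacing),
            "files": files,
        })
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_dataset(in_dir: str | Path) -> PhantomDataset:
    """Round-trip counterpart of :func:`write_dataset`."""
    import nibabel as nib

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    volumes = []
    for entry in manifest["volumes"]:
        channels = {seq: np.asarray(nib.load(in_dir / entry["files"][seq]).dataobj,
                                    dtype=np.float64)
                    for seq in SEQUENCES}
        volumes.append(LabeledVolume(
            channels=channels,
            brain_mask=np.asarray(nib.load(in_dir / entry["files"]["mask"]).dataobj,
                                  dtype=np.uint8),
            region_mask=np.asarray(nib.load(in_dir / entry["files"]["regions"]).dataobj,
                                   dtype=np.uint8),
            spacing=tuple(entry["spacing"]),
            class_label=int(entry["class"]),
            anatomy_seed=int(entry["anatomy_seed"]),
            domain_id=int(entry["domain"]),
        ))
    return PhantomDataset(volumes=volumes, pairs=manifest["pairs"])
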