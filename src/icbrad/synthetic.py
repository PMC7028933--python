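"""Seeded synthetic cohorts: volume trajectories, 3D tumor phantoms with an
injectable radiomic signal, expression tables and TCR repertoires.

The generator emulates a three-time-point preclinical MRI study of
checkpoint-blockade-treated orthotopic gliomas.  Animals are drawn from
four trajectory archetypes matching the observed growth patterns — direct
response (G1), pseudoprogression-then-response (G2), progression (G3) and
late progression (G4) — with a treated responder rate of 47.6% and a
responder mix of roughly 78:22 pseudoprogressors to direct responders.
Tumors are rendered as star-convex blobs: a sphere of matched volume whose
radius is modulated by band-limited spherical-harmonic noise (the
"irregularity"), filled with a correlated Gaussian intensity texture.

The label signal for the prediction pipeline is injected through the
MRI1→MRI2 change in surface irregularity: responders' irregularity drops by
δ while non-responders' rises by δ/4.  Because downstream delta features
are absolute differences, the *magnitudes* of the two shifts must differ —
an equal-and-opposite shift is invisible to |Δ| — so the responder shift is
deliberately the larger one.  With δ = 0, archetype growth factors between
MRI1 and MRI2 are matched across responders and non-responders, leaving the
observable scans with no label information (the null condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .immuno import Repertoire
from .radiomics import LabeledVolume, combine_timepoints, extract_all
from .response import (
    GrowthPattern,
    ResponseCriteriaConfig,
    VolumeTrajectory,
    classify_growth_pattern,
    classify_response,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ArchetypeParams:
    """Log-normal growth-factor model for one trajectory archetype.

    ``g21`` and ``g32`` are the v2/v1 and v3/v2 ratios (median and log-sd);
    sampling rejects draws whose growth pattern does not match
    ``target_pattern`` (bounded retries).
    """

    name: str
    target_pattern: GrowthPattern
    responder: bool
    g21_median: float
    g21_sigma: float
    g32_median: float
    g32_sigma: float
    cr_probability: float = 0.0

    def __post_init__(self) -> None:
        grew_12 = self.g21_median > 1.0
        grew_23 = self.g32_median > 1.0
        expected = {
            (False, False): GrowthPattern.G1,
            (True, False): GrowthPattern.G2,
            (True, True): GrowthPattern.G3,
            (False, True): GrowthPattern.G4,
        }[(grew_12, grew_23)]
        if expected is not self.target_pattern:
            raise ValueError(
                f"medians ({self.g21_median}, {self.g32_median}) inconsistent "
                f"with target pattern {self.target_pattern}"
            )


# MRI1→MRI2 growth distributions are matched between the pseudoprogressor
# and the progressor (and between G1 and G4) so that with no radiomic
# signal the first two scans carry no label information.
ARCHETYPES: dict[str, ArchetypeParams] = {
    "direct_responder": ArchetypeParams(
        "direct_responder", GrowthPattern.G1, True,
        g21_median=0.55, g21_sigma=0.25, g32_median=0.40, g32_sigma=0.30,
        cr_probability=0.05,
    ),
    "pseudoprogressor": ArchetypeParams(
        "pseudoprogressor", GrowthPattern.G2, True,
        g21_median=1.70, g21_sigma=0.25, g32_median=0.35, g32_sigma=0.30,
    ),
    "progressor": ArchetypeParams(
        "progressor", GrowthPattern.G3, False,
        g21_median=1.70, g21_sigma=0.25, g32_median=1.80, g32_sigma=0.30,
    ),
    "late_progressor": ArchetypeParams(
        "late_progressor", GrowthPattern.G4, False,
        g21_median=0.55, g21_sigma=0.25, g32_median=2.80, g32_sigma=0.30,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated treated cohort."""

    n_animals: int = 150
    arm: str = "ICB"
    responder_rate: float = 0.476
    responder_mix: tuple[tuple[str, float], ...] = (
        ("pseudoprogressor", 78 / 98), ("direct_responder", 20 / 98),
    )
    nonresponder_mix: tuple[tuple[str, float], ...] = (
        ("progressor", 0.8), ("late_progressor", 0.2),
    )
    baseline_volume_median: float = 12.0   # mm³ at d13
    baseline_volume_sigma: float = 0.4
    delta: float = 0.12                    # irregularity shift, responders
    noise_level: float = 0.02              # irregularity jitter sd
    base_irregularity: float = 0.25
    irregularity_sigma: float = 0.05
    texture_corr: float = 0.3              # mm, intensity correlation length
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.responder_rate <= 1):
            raise ValueError("responder_rate must be in [0, 1]")
        for mix in (self.responder_mix, self.nonresponder_mix):
            if abs(sum(w for _, w in mix) - 1.0) > 1e-9:
                raise ValueError("archetype mix weights must sum to 1")
            if any(name not in ARCHETYPES for name, _ in mix):
                raise ValueError("unknown archetype in mix")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def sample_trajectory(
    params: ArchetypeParams,
    seed: int | np.random.Generator,
    *,
    animal_id: str = "a0",
    arm: str = "ICB",
    baseline_median: float = 12.0,
    baseline_sigma: float = 0.4,
    require_response_match: bool = True,
    max_retries: int = 200,
) -> VolumeTrajectory:
    """Draw one trajectory of the given archetype (rejection sampling until
    the realized growth pattern — and, by default, responder status —
    matches the archetype)."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    for _ in range(max_retries):
        v1 = baseline_median * np.exp(rng.normal(0.0, baseline_sigma))
        g21 = params.g21_median * np.exp(rng.normal(0.0, params.g21_sigma))
        g32 = params.g32_median * np.exp(rng.normal(0.0, params.g32_sigma))
        v2 = v1 * g21
        v3 = v2 * g32
        if params.cr_probability > 0 and rng.random() < params.cr_probability:
            v3 = 0.0
        traj = VolumeTrajectory(animal_id=animal_id, v1=v1, v2=v2, v3=v3, arm=arm)
        if classify_growth_pattern(traj) is not params.target_pattern:
            continue
        if require_response_match:
            call = classify_response(traj)
            if call.responder is not params.responder:
                continue
        return traj
    raise RuntimeError(
        f"archetype {params.name!r}: no admissible trajectory in "
        f"{max_retries} draws (inconsistent parameters?)"
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic (theta = polar angle, phi = azimuth)."""
    if hasattr(special, "sph_harm_y"):
        y = special.sph_harm_y(l, abs(m), theta, phi)
    else:  # older scipy argument order
        y = special.sph_harm(abs(m), l, phi, theta)
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * y.real
    if m < 0:
        return np.sqrt(2.0) * (-1) ** m * y.imag
    return y.real


def sh_noise_coefficients(
    rng: np.random.Generator, l_max: int = 6, l_min: int = 2
) -> list[tuple[int, int, float]]:
    """Band-limited random coefficients (l, m, a_lm) with a gentle 1/l taper."""
    coeffs = []
    for l in range(l_min, l_max + 1):
        for m in range(-l, l + 1):
            coeffs.append((l, m, rng.normal(0.0, 1.0) / l))
    return coeffs


# The angular basis depends only on the grid geometry, so it is cached and
# shared by every phantom rendered on the same grid (one entry is enough:
# a cohort uses a single grid).
_BASIS_CACHE: dict = {}


def _sh_basis(shape: tuple[int, ...], spacing: tuple[float, ...],
              keys: tuple[tuple[int, int], ...]) -> dict:
    """Angular harmonics and radius field for the grid.  The angles depend
    only on the spacing *ratios*, so isotropic rescaling (used to fit large
    lesions) reuses the cached entry; ``rho`` is stored per unit of the
    smallest spacing and scaled by the caller."""
    s_min = min(spacing)
    ratio = tuple(s / s_min for s in spacing)
    cache_key = (shape, ratio, keys)
    if _BASIS_CACHE.get("key") == cache_key:
        return _BASIS_CACHE["value"]
    axes = [(np.arange(n) - (n - 1) / 2.0) * r for n, r in zip(shape, ratio)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(
            np.clip(np.where(rho > 0, Z / np.maximum(rho, 1e-12), 1.0), -1, 1)
        )
    phi = np.arctan2(Y, X)
    value = {"rho_unit": rho}
    for l, m in keys:
        value[(l, m)] = _real_sph_harm(l, m, theta, phi)
    _BASIS_CACHE["key"] = cache_key
    _BASIS_CACHE["value"] = value
    return value


def render_phantom(
    volume: float,
    irregularity: float,
    texture_corr: float = 0.3,
    seed: int | np.random.Generator = 0,
    spacing: Sequence[float] = (0.1, 0.1, 0.1),
    shape: Sequence[int] = (64, 64, 64),
    *,
    coefficients: Sequence[tuple[int, int, float]] | None = None,
    base_intensity: float = 100.0,
    texture_sd: float = 15.0,
    background_intensity: float = 20.0,
    volume_tolerance: float = 0.03,
) -> LabeledVolume:
    """Voxelize a star-convex tumor blob of the requested volume (mm³).

    A sphere of matched volume is perturbed by band-limited
    spherical-harmonic radial noise of relative RMS amplitude
    ``irregularity`` and voxelized on the grid; the base radius is rescaled
    until the realized voxel volume is within ``volume_tolerance`` of the
    request.  Intensities are a constant plus a correlated Gaussian field
    (correlation length ``texture_corr`` mm) inside the mask.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(s) for s in shape)
    vv = float(np.prod(spacing))
    if volume < vv:
        raise ValueError(f"requested volume {volume} mm³ is below one voxel")

    coeffs = list(coefficients) if coefficients is not None else sh_noise_coefficients(rng)
    basis = _sh_basis(shape, spacing, tuple((l, m) for l, m, _ in coeffs))
    rho = basis["rho_unit"] * min(spacing)
    f = np.zeros(shape)
    for l, m, a in coeffs:
        f += a * basis[(l, m)]
    rms = float(np.sqrt((f ** 2).mean()))
    if rms > 0:
        f /= rms

    r0 = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(12):
        radius_field = r0 * np.clip(1.0 + irregularity * f, 0.2, None)
        mask = rho <= radius_field
        realized = mask.sum() * vv
        if realized <= 0:
            r0 *= 1.3
            continue
        if abs(realized - volume) / volume <= volume_tolerance * 0.5:
            break
        r0 *= (volume / realized) ** (1.0 / 3.0)
    realized = mask.sum() * vv
    if realized <= 0 or abs(realized - volume) / volume > volume_tolerance:
        raise RuntimeError(
            f"phantom volume {realized:.2f} mm³ outside tolerance of "
            f"requested {volume:.2f} mm³ (grid too small?)"
        )
    if mask.any(axis=(1, 2))[[0, -1]].any() or mask.any(axis=(0, 2))[[0, -1]].any() \
            or mask.any(axis=(0, 1))[[0, -1]].any():
        raise RuntimeError("phantom touches the grid boundary; enlarge the grid")

    sigma_vox = [max(texture_corr / s, 1e-6) for s in spacing]
    noise = rng.normal(0.0, 1.0, size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    intensities = np.where(
        mask, base_intensity + texture_sd * smooth,
        background_intensity + 5.0 * rng.normal(0.0, 1.0, size=shape),
    )
    return LabeledVolume(intensities, mask, spacing)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    spec: CohortSpec
    volumes: pd.DataFrame
    calls: pd.DataFrame
    features: pd.DataFrame | None = None
    phantoms: dict[tuple[str, int], LabeledVolume] = field(default_factory=dict)

    @property
    def labels(self) -> pd.DataFrame:
        return self.calls[["animal_id", "responder"]].copy()


def _choose(rng: np.random.Generator, mix: tuple[tuple[str, float], ...]) -> str:
    names = [n for n, _ in mix]
    w = np.array([p for _, p in mix])
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def _fit_spacing(volume: float, irregularity: float, spec: CohortSpec) -> tuple[float, ...]:
    """Voxel spacing at which the blob fits the grid: the default spacing,
    coarsened isotropically for lesions too large for the field of view (so
    volumes stay faithful at the cost of resolution)."""
    r0 = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_need = r0 * (1.0 + 3.2 * irregularity)  # radial noise peaks ~3 RMS units
    n_min = min(spec.grid_shape)
    s_need = r_need / (n_min / 2.0 - 3.0)
    factor = max(1.0, s_need / min(spec.spacing))
    return tuple(s * factor for s in spec.spacing)


def generate_cohort(
    spec: CohortSpec,
    *,
    render: bool = True,
    time_points: Sequence[int] = (1, 2, 3),
    extract_features: bool = False,
    keep_phantoms: bool = False,
    outdir: str | Path | None = None,
) -> CohortData:
    """Generate a full synthetic cohort.

    Per animal: archetype per the responder-rate/mix, a trajectory, and
    (optionally) phantoms at the requested time points whose surface
    irregularity carries the response signal.  Labels are the volumetric
    response calls recomputed from the generated volume table.  With
    ``extract_features`` the per-animal baseline+delta radiomic vector
    (846 values from MRI1 and MRI2) is extracted on the fly.
    """
    rng = np.random.default_rng(spec.seed)
    trajs: list[VolumeTrajectory] = []
    for i in range(spec.n_animals):
        responder = rng.random() < spec.responder_rate
        mix = spec.responder_mix if responder else spec.nonresponder_mix
        params = ARCHETYPES[_choose(rng, mix)]
        trajs.append(
            sample_trajectory(
                params, rng, animal_id=f"{spec.arm}-{i:04d}", arm=spec.arm,
                baseline_median=spec.baseline_volume_median,
                baseline_sigma=spec.baseline_volume_sigma,
            )
        )
    volumes = pd.DataFrame(
        {
            "animal_id": [t.animal_id for t in trajs],
            "arm": [t.arm for t in trajs],
            "v1": [t.v1 for t in trajs],
            "v2": [t.v2 for t in trajs],
            "v3": [t.v3 for t in trajs],
        }
    )
    calls = [classify_response(t) for t in trajs]
    calls_df = pd.DataFrame(
        {
            "animal_id": [c.animal_id for c in calls],
            "category": [c.category.value for c in calls],
            "responder": [c.responder for c in calls],
            "growth_pattern": [c.growth_pattern.value for c in calls],
        }
    )

    phantoms: dict[tuple[str, int], LabeledVolume] = {}
    feat_rows: list[pd.Series] = []
    feat_ids: list[str] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if render or extract_features:
        for t, call in zip(trajs, calls):
            child = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
            coeffs = sh_noise_coefficients(child)
            irr1 = float(np.clip(
                child.normal(spec.base_irregularity, spec.irregularity_sigma),
                0.08, 0.45,
            ))
            shift = -spec.delta if call.responder else spec.delta / 4.0
            irr2 = float(np.clip(
                irr1 + shift + child.normal(0.0, spec.noise_level), 0.02, 0.6
            ))
            irr3 = float(np.clip(irr2 + child.normal(0.0, spec.noise_level), 0.02, 0.6))
            irr = {1: irr1, 2: irr2, 3: irr3}
            vols = {1: t.v1, 2: t.v2, 3: t.v3}
            per_tp: dict[int, LabeledVolume] = {}
            for tp in time_points:
                v = vols[tp]
                if v <= 0:  # complete response: empty scan
                    lv = LabeledVolume(
                        np.full(spec.grid_shape, 20.0),
                        np.zeros(spec.grid_shape, dtype=bool),
                        spec.spacing,
                    )
                else:
                    lv = render_phantom(
                        v, irr[tp], spec.texture_corr, child,
                        spacing=_fit_spacing(v, irr[tp], spec),
                        shape=spec.grid_shape,
                        coefficients=coeffs,
                    )
                per_tp[tp] = lv
                if keep_phantoms:
                    phantoms[(t.animal_id, tp)] = lv
                if outdir is not None:
                    _write_nifti(lv, outdir, t.animal_id, tp)
            if extract_features and 1 in per_tp and 2 in per_tp:
                f1 = extract_all(per_tp[1])
                f2 = extract_all(per_tp[2])
                feat_rows.append(combine_timepoints(f1, f2))
                feat_ids.append(t.animal_id)

    features = None
    if extract_features:
        features = pd.DataFrame(feat_rows, index=feat_ids)
        features.index.name = "animal_id"

    if outdir is not None:
        volumes.to_csv(outdir / "volumes.csv", index=False)
        calls_df.to_csv(outdir / "labels.csv", index=False)
        spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(spec).items()}
        (outdir / "spec.json").write_text(json.dumps(spec_dict, indent=1, default=str))
        if features is not None:
            features.to_csv(outdir / "features.csv")

    return CohortData(spec=spec, volumes=volumes, calls=calls_df,
                      features=features, phantoms=phantoms)


def _write_nifti(lv: LabeledVolume, outdir: Path, animal_id: str, tp: int) -> None:
    import nibabel as nib

    affine = np.diag(list(lv.spacing) + [1.0])
    nib.save(nib.Nifti1Image(lv.intensities.astype(np.float32), affine),
             outdir / f"{animal_id}_mri{tp}_t2.nii.gz")
    nib.save(nib.Nifti1Image(lv.mask.astype(np.uint8), affine),
             outdir / f"{animal_id}_mri{tp}_mask.nii.gz")


# ---------------------------------------------------------------------------
# expression and repertoires
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int = 200,
    n_samples_per_group: tuple[int, int] = (4, 3),
    signature_size: int = 20,
    pro_inflammatory_effect: float = 1.0,
    anti_inflammatory_effect: float = 1.0,
    seed: int = 0,
    base_mean: float = 50.0,
    dispersion: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.Series]:
    """Log-normal expression counts for two groups (R and NR) with optional
    multiplicative effects on the pro-/anti-inflammatory gene sets in the
    responder group.

    Returns (genes × samples table, gene sets, sample→group labels).
    """
    if n_genes < 2 * signature_size:
        raise ValueError("n_genes too small for the two signatures")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    samples = [f"R{i}" for i in range(n_samples_per_group[0])] + [
        f"NR{i}" for i in range(n_samples_per_group[1])
    ]
    groups = pd.Series(["R"] * n_samples_per_group[0] + ["NR"] * n_samples_per_group[1],
                       index=samples)
    base = base_mean * np.exp(rng.normal(0.0, dispersion, size=(n_genes, len(samples))))
    gene_sets = {
        "pro_inflammatory": genes[:signature_size],
        "anti_inflammatory": genes[signature_size: 2 * signature_size],
    }
    is_r = (groups == "R").to_numpy()
    base[:signature_size, is_r] *= pro_inflammatory_effect
    base[signature_size: 2 * signature_size, is_r] *= anti_inflammatory_effect
    return pd.DataFrame(base, index=genes, columns=samples), gene_sets, groups


def _random_cdr3(rng: np.random.Generator, length: int | None = None) -> str:
    n = int(length) if length is not None else int(rng.integers(10, 17))
    middle = "".join(rng.choice(_AA, size=n - 2))
    return "C" + middle + "F"


def generate_repertoire(
    r_clones: int,
    concentration: float,
    seed: int | np.random.Generator = 0,
    *,
    sample: str = "s0",
    total_counts: int = 10_000,
) -> Repertoire:
    """One repertoire: clone frequencies from a symmetric Dirichlet with the
    given concentration (small → oligoclonal) and multinomial counts."""
    if r_clones < 1:
        raise ValueError("need at least one clone")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    p = rng.dirichlet(np.full(r_clones, concentration))
    counts = rng.multinomial(total_counts, p)
    seqs: set[str] = set()
    while len(seqs) < r_clones:
        seqs.add(_random_cdr3(rng))
    clones = {s: int(c) + 1 for s, c in zip(sorted(seqs), counts)}
    return Repertoire.from_counts(sample, clones)


def generate_repertoires(
    n_samples: int,
    r_clones: int = 100,
    concentration: float = 1.0,
    shared_motif: bool = False,
    motif_samples: Sequence[int] | None = None,
    seed: int = 0,
    total_counts: int = 10_000,
) -> list[Repertoire]:
    """A set of repertoires, optionally with a planted length-matched CDR3
    motif (≤ 1 substitution between carriers) across designated samples."""
    rng = np.random.default_rng(seed)
    reps = [
        generate_repertoire(
            r_clones, concentration, rng, sample=f"s{i}", total_counts=total_counts
        )
        for i in range(n_samples)
    ]
    if shared_motif:
        carriers = list(motif_samples) if motif_samples is not None else list(
            range(min(3, n_samples))
        )
        base = _random_cdr3(rng, length=14)
        for k, i in enumerate(carriers):
            seq = base
            if k > 0 and rng.random() < 0.5:  # at most one substitution
                pos = int(rng.integers(1, len(base) - 1))
                repl = str(rng.choice(_AA))
                seq = base[:pos] + repl + base[pos + 1:]
            counts = dict(reps[i].clones)
            counts[seq] = counts.get(seq, 0) + 50
            reps[i] = Repertoire.from_counts(reps[i].sample, counts)
    return reps
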