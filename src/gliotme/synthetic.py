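"""Synthetic HLA-stained tissue-microarray (TMA) core generator.

Real cores are circular tissue discs carrying a brown DAB-like immunostain
(here standing for HLA-DP/-DQ/-DR on myeloid cells) over a blue
hematoxylin counterstain.  The generator plants a known ground truth at
three levels:

* **phenotypes** (P1..P8): local cell appearance classes differing in
  radius, shape (round / ameboid / ramified) and stain optical density;
* **neighborhoods** (N1..N8): contiguous tissue regions with a
  characteristic phenotype mixture and cell density;
* **grade structure**: per WHO grade (0 = normal tissue, 1-4 = glioma), a
  Dirichlet concentration vector over neighborhoods so that neighborhood
  abundance depends on grade.

Rendering uses Beer-Lambert mixing of two fixed RGB absorbance vectors
(DAB-like brown and hematoxylin-like blue), which reproduces the
two-colour statistics of single-stain immunohistochemistry without
modelling optics.  All randomness flows through one explicit
``numpy.random.Generator``; identical ``(config, seed)`` gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhenotypeSpec",
    "NeighborhoodSpec",
    "GradeProfile",
    "CoreTruth",
    "SyntheticCohort",
    "CohortConfig",
    "default_phenotypes",
    "default_neighborhoods",
    "default_grade_profiles",
    "paper_default_config",
    "small_test_config",
    "easy_phenotype_config",
    "patch_truth_labels",
    "generate_core",
    "generate_cohort",
    "sample_abundance_cohort",
]

# Ruifrok-Johnston-style unit absorbance vectors (R, G, B)
_ABS_DAB = np.array([0.27, 0.57, 0.78])
_ABS_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
_ABS_DAB /= np.linalg.norm(_ABS_DAB)
_ABS_HEMATOXYLIN /= np.linalg.norm(_ABS_HEMATOXYLIN)


@dataclass(frozen=True)
class PhenotypeSpec:
    """One cell appearance class (P1..P8)."""

    id: str
    cell_radius: tuple[float, float]  # min/max radius, pixels
    shape: str  # round | ameboid | ramified
    stain_od: tuple[float, float]  # mean, sd of brown optical density
    counter_od: float = 0.35  # blue counterstain OD of the nucleus

    def __post_init__(self) -> None:
        if self.cell_radius[0] <= 0:
            raise ValueError("cell_radius must be positive")
        if not 0.0 <= self.stain_od[0] <= 1.0:
            raise ValueError("stain_od mean must lie in [0, 1]")
        if self.shape not in ("round", "ameboid", "ramified"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A recurring spatial phenotype composition (N1..N8)."""

    id: str
    phenotype_mix: tuple[float, ...]  # over phenotypes, sums to 1
    cluster_scale: float  # spatial correlation length, px
    cell_density: float  # cells per 10^4 px^2

    def __post_init__(self) -> None:
        mix = np.asarray(self.phenotype_mix)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("phenotype_mix must be nonnegative and sum to 1")
        if self.cluster_scale <= 0:
            raise ValueError("cluster_scale must be positive")


@dataclass(frozen=True)
class GradeProfile:
    """Cohort composition and neighborhood preference of one WHO grade."""

    grade: int
    n_images: int
    neighborhood_weights: tuple[float, ...]  # Dirichlet concentrations over N

    def __post_init__(self) -> None:
        if self.grade not in range(5):
            raise ValueError("grade must be in 0..4")
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if min(self.neighborhood_weights) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


@dataclass
class CoreTruth:
    """Planted ground truth aligned pixelwise with a rendered core."""

    phenotype_map: np.ndarray  # int, -1 = no cell
    neighborhood_map: np.ndarray  # int, -1 = outside tissue disc
    tissue_mask: np.ndarray  # bool
    neighborhood_abundance: np.ndarray  # fraction of tissue pixels per N

    def __post_init__(self) -> None:
        if self.phenotype_map.shape != self.neighborhood_map.shape:
            raise ValueError("truth maps must share a shape")


@dataclass
class SyntheticCohort:
    images: list[np.ndarray]
    labels: list[int]
    image_ids: list[str]
    truths: list[CoreTruth]
    seed: int

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"image_id": self.image_ids, "grade": self.labels})

    def truth_abundance_matrix(self) -> pd.DataFrame:
        """Per-image planted neighborhood abundance (rows sum to 1)."""
        rows = [t.neighborhood_abundance for t in self.truths]
        n_cols = len(rows[0]) if rows else 0
        mat = pd.DataFrame(
            rows,
            index=self.image_ids,
            columns=[f"N{i + 1}" for i in range(n_cols)],
        )
        mat["grade"] = self.labels
        return mat


@dataclass
class CohortConfig:
    phenotypes: list[PhenotypeSpec]
    neighborhoods: list[NeighborhoodSpec]
    grade_profiles: list[GradeProfile]
    image_size: int = 256
    separation: float = 1.0  # 0 => identical grade profiles, 1 => as given

    def __post_init__(self) -> None:
        grades = sorted(p.grade for p in self.grade_profiles)
        if grades != [0, 1, 2, 3, 4]:
            raise ValueError("config must list exactly one profile per grade 0..4")
        n_ph = len(self.phenotypes)
        for nb in self.neighborhoods:
            if len(nb.phenotype_mix) != n_ph:
                raise ValueError(
                    f"neighborhood {nb.id}: phenotype_mix length "
                    f"{len(nb.phenotype_mix)} != {n_ph} phenotypes"
                )
        for gp in self.grade_profiles:
            if len(gp.neighborhood_weights) != len(self.neighborhoods):
                raise ValueError(
                    f"grade {gp.grade}: weight length != {len(self.neighborhoods)}"
                )

    def effective_weights(self) -> dict[int, np.ndarray]:
        """Grade concentration vectors after the separability dial.

        ``separation`` linearly interpolates each grade's concentration
        vector between the cohort-mean vector (0, grades indistinguishable)
        and the configured one (1, full planted separation).
        """
        w = {p.grade: np.asarray(p.neighborhood_weights, float) for p in self.grade_profiles}
        mean = np.mean(list(w.values()), axis=0)
        s = float(self.separation)
        return {g: (1 - s) * mean + s * v for g, v in w.items()}


# ---------------------------------------------------------------------------
# Default specifications


def default_phenotypes() -> list[PhenotypeSpec]:
    """Eight phenotypes spanning stain intensity and morphology.

    Low ids are weakly stained round cells (resting microglia-like), high
    ids are intensely stained ameboid/ramified cells (activated
    myeloid-like), mirroring the appearance classes single-stain HLA
    images exhibit.
    """
    return [
        PhenotypeSpec("P1", (2.5, 4.0), "round", (0.05, 0.02)),
        PhenotypeSpec("P2", (3.0, 5.0), "round", (0.15, 0.04)),
        PhenotypeSpec("P3", (3.5, 5.5), "ameboid", (0.55, 0.08)),
        PhenotypeSpec("P4", (4.0, 6.5), "ameboid", (0.80, 0.08)),
        PhenotypeSpec("P5", (3.0, 5.0), "ramified", (0.35, 0.06)),
        PhenotypeSpec("P6", (2.5, 4.5), "ramified", (0.60, 0.08)),
        PhenotypeSpec("P7", (5.0, 7.5), "round", (0.45, 0.08)),
        PhenotypeSpec("P8", (2.0, 3.5), "round", (0.90, 0.05)),
    ]


def default_neighborhoods() -> list[NeighborhoodSpec]:
    """Eight neighborhoods, each dominated by a few phenotypes."""

    def mix(**kv: float) -> tuple[float, ...]:
        v = np.zeros(8)
        for key, val in kv.items():
            v[int(key[1]) - 1] = val
        return tuple(v / v.sum())

    return [
        NeighborhoodSpec("N1", mix(p1=0.7, p2=0.3), 40.0, 6.0),
        NeighborhoodSpec("N2", mix(p4=0.6, p3=0.3, p8=0.1), 40.0, 14.0),
        NeighborhoodSpec("N3", mix(p3=0.6, p6=0.4), 40.0, 10.0),
        NeighborhoodSpec("N4", mix(p4=0.5, p7=0.5), 40.0, 12.0),
        NeighborhoodSpec("N5", mix(p5=0.7, p1=0.3), 40.0, 7.0),
        NeighborhoodSpec("N6", mix(p6=0.6, p5=0.4), 40.0, 9.0),
        NeighborhoodSpec("N7", mix(p2=0.6, p7=0.4), 40.0, 8.0),
        NeighborhoodSpec("N8", mix(p8=0.5, p3=0.25, p4=0.25), 40.0, 12.0),
    ]


def default_grade_profiles() -> list[GradeProfile]:
    """Study-cohort composition with grade-coupled neighborhood weights.

    Image counts follow the study cohort (21 normal, 24/84/26/51 WHO
    grades 1-4; 206 total).  Concentrations shift smoothly from
    weak-stain neighborhoods (N1, N5, N7) in normal tissue toward the
    dense, intensely stained N2/N4/N8 in grade 4, so that N2 abundance
    grows monotonically with grade — the pattern differential analysis
    should rediscover.  Adjacent grades 2 and 3 are given deliberately
    overlapping profiles.
    """
    return [
        GradeProfile(0, 21, (8.0, 0.3, 0.5, 0.4, 6.0, 1.5, 4.0, 0.3)),
        GradeProfile(1, 24, (5.0, 1.0, 1.5, 0.8, 4.5, 2.5, 3.5, 0.7)),
        GradeProfile(2, 84, (2.0, 3.0, 2.5, 2.0, 2.0, 2.5, 1.5, 1.5)),
        GradeProfile(3, 26, (1.5, 4.0, 2.5, 2.8, 1.5, 2.0, 1.0, 2.2)),
        GradeProfile(4, 51, (0.5, 8.0, 1.5, 4.0, 0.5, 1.0, 0.4, 3.5)),
    ]


def paper_default_config(image_size: int = 256, separation: float = 1.0) -> CohortConfig:
    """The study-cohort configuration: 206 images split 21/24/84/26/51."""
    return CohortConfig(
        default_phenotypes(),
        default_neighborhoods(),
        default_grade_profiles(),
        image_size=image_size,
        separation=separation,
    )


def easy_phenotype_config(
    n_per_grade: int = 3, image_size: int = 128, cell_density: float = 120.0
) -> CohortConfig:
    """Three well-separated phenotypes in pure neighborhoods.

    The benign recovery fixture: P1 is unstained (counterstain only),
    P2 a large ameboid moderately stained cell, P3 a small intensely
    stained cell; each neighborhood carries exactly one phenotype.
    Embedding-based clustering should recover the planted phenotypes
    nearly perfectly here.
    """
    phenos = [
        PhenotypeSpec("P1", (2.5, 3.5), "round", (0.02, 0.01), counter_od=0.6),
        PhenotypeSpec("P2", (5.0, 7.0), "ameboid", (0.4, 0.03)),
        PhenotypeSpec("P3", (3.0, 4.0), "round", (1.0, 0.02)),
    ]

    def one_hot(i: int) -> tuple[float, ...]:
        v = np.zeros(3)
        v[i] = 1.0
        return tuple(v)

    nbs = [
        NeighborhoodSpec(f"N{i + 1}", one_hot(i), 40.0, cell_density) for i in range(3)
    ]
    profiles = [
        GradeProfile(
            g, n_per_grade, tuple(4.0 if g % 3 == i else 0.5 for i in range(3))
        )
        for g in range(5)
    ]
    return CohortConfig(phenos, nbs, profiles, image_size=image_size)


def strong_coupling_config(
    n_per_grade: int = 16, image_size: int = 256, scale: float = 3.0
) -> CohortConfig:
    """Grade-balanced cohort with tightened grade-neighborhood coupling.

    The study-default grade profiles with all Dirichlet concentrations
    multiplied by ``scale``: relative neighborhood preferences are
    unchanged but within-grade composition variance shrinks, giving the
    benign regime for pipeline-recovery checks (extreme grade pairs
    clearly separable; the overlapping grades 2 and 3 remain hard).
    """
    profiles = [
        GradeProfile(
            p.grade, n_per_grade, tuple(np.asarray(p.neighborhood_weights) * scale)
        )
        for p in default_grade_profiles()
    ]
    return CohortConfig(
        default_phenotypes(), default_neighborhoods(), profiles, image_size=image_size
    )


def patch_truth_labels(
    truths: dict[str, CoreTruth],
    patches,
    min_coverage: float = 0.1,
    min_purity: float = 0.8,
) -> np.ndarray:
    """Planted phenotype label per patch, -1 when none applies.

    A patch carries the modal phenotype of its cell pixels provided
    cells cover at least ``min_coverage`` of the patch and the modal
    phenotype holds at least ``min_purity`` of those pixels — i.e. the
    patch actually displays one phenotype.
    """
    labels = []
    for p in patches:
        x, y = p.center
        s = p.size // 2
        block = truths[p.image_id].phenotype_map[y - s : y + s, x - s : x + s]
        vals = block[block >= 0]
        if vals.size < min_coverage * block.size:
            labels.append(-1)
            continue
        counts = np.bincount(vals)
        if counts.max() / counts.sum() < min_purity:
            labels.append(-1)
            continue
        labels.append(int(counts.argmax()))
    return np.asarray(labels)


def small_test_config(
    n_per_grade: int = 4, image_size: int = 128, separation: float = 1.0
) -> CohortConfig:
    """A 5x``n_per_grade`` desk-scale cohort with the default specs."""
    profiles = [
        GradeProfile(p.grade, n_per_grade, p.neighborhood_weights)
        for p in default_grade_profiles()
    ]
    return CohortConfig(
        default_phenotypes(),
        default_neighborhoods(),
        profiles,
        image_size=image_size,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# Rendering


def _cell_od_stamp(
    pheno: PhenotypeSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one cell: (brown OD patch, blue OD patch)."""
    radius = rng.uniform(*pheno.cell_radius)
    r_int = max(1, int(np.ceil(radius * (2.2 if pheno.shape == "ramified" else 1.3))))
    size = 2 * r_int + 1
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    rr = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)

    if pheno.shape == "round":
        body = rr <= radius
    elif pheno.shape == "ameboid":
        # lumpy boundary: radius modulated by low-order harmonics
        wobble = 1.0 + 0.25 * np.cos(3 * theta + rng.uniform(0, 2 * np.pi))
        wobble += 0.15 * np.cos(5 * theta + rng.uniform(0, 2 * np.pi))
        body = rr <= radius * wobble
    else:  # ramified: small soma plus thin processes
        body = rr <= radius * 0.6
        n_proc = rng.integers(3, 6)
        for ang in rng.uniform(0, 2 * np.pi, n_proc):
            along = rr * np.cos(theta - ang)
            across = rr * np.sin(theta - ang)
            body |= (along > 0) & (along <= radius * 2.0) & (np.abs(across) <= 0.8)

    od = float(np.clip(rng.normal(*pheno.stain_od), 0.0, 1.2))
    # near-uniform chromogen density with a soft rim
    soft = np.clip(2.5 * (1.0 - rr / (radius * 1.05 + 1e-9)), 0.0, 1.0)
    soft = np.clip(soft, 0.5, 1.0)
    brown = np.where(body, od * soft, 0.0)
    blue = np.where(rr <= radius * 0.55, pheno.counter_od, 0.0)  # nucleus
    return brown, blue


def _od_to_rgb(brown: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Beer-Lambert: transmitted intensity = exp(-OD x absorbance)."""
    od_stack = (
        brown[..., None] * _ABS_DAB[None, None, :]
        + blue[..., None] * _ABS_HEMATOXYLIN[None, None, :]
    )
    rgb = np.exp(-od_stack)
    return (np.clip(rgb, 0.0, 1.0) * 255).round().astype(np.uint8)


def generate_core(
    profile: GradeProfile,
    nbhd_specs: list[NeighborhoodSpec],
    pheno_specs: list[PhenotypeSpec],
    size: int = 256,
    seed: int | np.random.Generator = 0,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, CoreTruth]:
    """Render one circular TMA core and its planted truth maps.

    Region seeds are drawn from a Poisson process over the tissue disc,
    labelled with neighborhoods via a Dirichlet-multinomial draw from the
    grade profile, and grown into contiguous regions by nearest-seed
    (Voronoi) partition.  Cells are then scattered per region at the
    neighborhood's density with phenotypes from its mixture.
    """
    if size < 64:
        raise ValueError("core size must be >= 64 pixels")
    for nb in nbhd_specs:
        if len(nb.phenotype_mix) != len(pheno_specs):
            raise ValueError(
                f"neighborhood {nb.id}: mix length {len(nb.phenotype_mix)} "
                f"!= {len(pheno_specs)} phenotypes"
            )
    conc = np.asarray(
        profile.neighborhood_weights if weights is None else weights, float
    )
    if conc.shape != (len(nbhd_specs),):
        raise ValueError("weight vector length must equal the number of neighborhoods")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    center = (size - 1) / 2.0
    disc_r = 0.47 * size
    yy, xx = np.mgrid[0:size, 0:size]
    tissue = (yy - center) ** 2 + (xx - center) ** 2 <= disc_r**2

    # --- neighborhood regions -------------------------------------------
    scale = float(np.mean([nb.cluster_scale for nb in nbhd_specs]))
    expected_seeds = max(3, int(np.pi * disc_r**2 / scale**2))
    n_seed = max(1, rng.poisson(expected_seeds))
    pts = []
    while len(pts) < n_seed:
        cand = rng.uniform(0, size, size=(n_seed * 2, 2))
        inside = (cand[:, 0] - center) ** 2 + (cand[:, 1] - center) ** 2 <= disc_r**2
        pts.extend(cand[inside].tolist())
    pts = np.array(pts[:n_seed])  # (y, x)

    mixture = rng.dirichlet(conc)
    seed_labels = rng.choice(len(nbhd_specs), size=n_seed, p=mixture)

    from scipy.spatial import cKDTree

    _, nearest = cKDTree(pts).query(np.column_stack([yy.ravel(), xx.ravel()]))
    nbhd_map = np.where(
        tissue, seed_labels[nearest.reshape(size, size)], -1
    ).astype(np.int32)

    # --- cells ----------------------------------------------------------
    brown = np.zeros((size, size))
    blue = np.full((size, size), 0.0)
    blue[tissue] = 0.12  # faint diffuse counterstain over the disc
    pheno_map = np.full((size, size), -1, dtype=np.int32)

    for nb_idx, nb in enumerate(nbhd_specs):
        region = nbhd_map == nb_idx
        area = int(region.sum())
        if area == 0:
            continue
        n_cells = rng.poisson(nb.cell_density * area / 1e4)
        if n_cells == 0:
            continue
        ys, xs = np.nonzero(region)
        mix = np.asarray(nb.phenotype_mix)
        phenos = rng.choice(len(pheno_specs), size=n_cells, p=mix)
        # sequential placement with soft exclusion: cells form a monolayer,
        # so a candidate too close to an accepted cell is re-drawn
        placed: list[tuple[int, int, float]] = []
        centers = []
        for ph in phenos:
            r_mean = float(np.mean(pheno_specs[ph].cell_radius))
            for _ in range(8):  # bounded rejection attempts
                j = int(rng.integers(0, area))
                cy, cx = int(ys[j]), int(xs[j])
                if all(
                    (cy - py) ** 2 + (cx - px) ** 2 >= (0.8 * (r_mean + pr)) ** 2
                    for py, px, pr in placed
                ):
                    break
            placed.append((cy, cx, r_mean))
            centers.append((cy, cx, ph))
        for cy, cx, ph in centers:
            b_patch, n_patch = _cell_od_stamp(pheno_specs[ph], rng)
            r = b_patch.shape[0] // 2
            y0, y1 = max(0, cy - r), min(size, cy + r + 1)
            x0, x1 = max(0, cx - r), min(size, cx + r + 1)
            py0, px0 = y0 - (cy - r), x0 - (cx - r)
            sub_b = b_patch[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]
            sub_n = n_patch[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]
            brown[y0:y1, x0:x1] += sub_b
            blue[y0:y1, x0:x1] += sub_n
            body = sub_b > 0
            pheno_map[y0:y1, x0:x1][body] = ph

    brown[~tissue] = 0.0
    blue[~tissue] = 0.0
    pheno_map[~tissue] = -1

    image = _od_to_rgb(brown, blue)
    counts = np.bincount(nbhd_map[tissue], minlength=len(nbhd_specs)).astype(float)
    truth = CoreTruth(
        phenotype_map=pheno_map,
        neighborhood_map=nbhd_map,
        tissue_mask=tissue,
        neighborhood_abundance=counts / counts.sum(),
    )
    return image, truth


def generate_cohort(
    config: CohortConfig, seed: int, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate a full cohort; optionally write PNGs + labels CSV + truth.

    Per-grade image counts follow the config exactly.  With ``out_dir``
    set, writes ``<id>.png`` per core, ``labels.csv`` with columns
    ``image_id,grade``, per-image truth-map ``.npz`` files and a region
    table ``truth_abundance.csv``.
    """
    rng = np.random.default_rng(seed)
    weights = config.effective_weights()
    images: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    truths: list[CoreTruth] = []
    for gp in sorted(config.grade_profiles, key=lambda p: p.grade):
        for i in range(gp.n_images):
            img, truth = generate_core(
                gp,
                config.neighborhoods,
                config.phenotypes,
                size=config.image_size,
                seed=rng,
                weights=weights[gp.grade],
            )
            images.append(img)
            labels.append(gp.grade)
            ids.append(f"g{gp.grade}_{i:03d}")
            truths.append(truth)

    cohort = SyntheticCohort(images, labels, ids, truths, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, iid in zip(images, ids):
            Image.fromarray(img).save(out / f"{iid}.png")
        cohort.labels_frame().to_csv(out / "labels.csv", index=False)
        cohort.truth_abundance_matrix().to_csv(out / "truth_abundance.csv")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for iid, t in zip(ids, truths):
            np.savez(
                truth_dir / f"{iid}.npz",
                phenotype_map=t.phenotype_map,
                neighborhood_map=t.neighborhood_map,
                tissue_mask=t.tissue_mask,
            )
        meta = {"seed": seed, "n_images": len(ids), "image_size": config.image_size}
        (out / "manifest.json").write_text(json.dumps(meta, indent=2))
    return cohort


def sample_abundance_cohort(
    config: CohortConfig, seed: int, noise_sd: float = 0.0
) -> pd.DataFrame:
    """Draw per-image neighborhood abundance vectors without rendering.

    Samples each image's composition directly from its grade's Dirichlet
    concentration vector (the same distribution the renderer uses for
    region labelling), which makes large calibration simulations — e.g.
    false-positive-rate checks over hundreds of cohorts — cheap.
    """
    rng = np.random.default_rng(seed)
    weights = config.effective_weights()
    rows, grades, ids = [], [], []
    for gp in sorted(config.grade_profiles, key=lambda p: p.grade):
        for i in range(gp.n_images):
            v = rng.dirichlet(weights[gp.grade])
            if noise_sd > 0:
                v = np.clip(v + rng.normal(0, noise_sd, v.size), 1e-12, None)
                v /= v.sum()
            rows.append(v)
            grades.append(gp.grade)
            ids.append(f"g{gp.grade}_{i:03d}")
    out = pd.DataFrame(
        rows, index=ids, columns=[f"N{i + 1}" for i in range(len(config.neighborhoods))]
    )
    out["grade"] = grades
    return out
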