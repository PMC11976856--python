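"""Seeded generators for every input the pipeline consumes.

The plate generator reproduces the statistical structure the potency stage
assumes: positive signals, multiplicative lognormal well noise, an
experiment-level scale factor (plate effect, cancels under fold-effect
normalization), and a power-law dose trend ``(dose + 1) ** beta``.
Descriptor tables and marker panels plant a column with an exact requested
sample correlation against a supplied consensus-potency vector, so the
association screen has a known top hit.  Protein matrices plant log2
abundance shifts into named gene sets for the enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nanopotency.enrichment import GeneSetCollection
from nanopotency.errors import DesignError, GenerationError
from nanopotency.potency import ENDPOINTS, PLATE_COLUMNS

#: Two-fold default dose series (ug/cm^2) spanning the study's 0-100 range.
DEFAULT_DOSES = (0.0, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0)

#: Assay signal directionality: LDH release rises with dose, ATP and CTB fall.
ASSAY_SIGN = {"LDH": +1.0, "ATP": -1.0, "CTB": -1.0}

_PHYSCHEM_RANGES = {
    "tem_size": (10.0, 120.0),
    "bet_sa": (9.0, 160.0),
    "dls_size": (30.0, 1200.0),
    "pdi": (0.1, 0.75),
    "zeta_potential": (-45.0, 45.0),
    "tga_groups": (150.0, 1300.0),
    "total_metals": (400.0, 650000.0),
    "transition_metals": (350.0, 620000.0),
    "transition_metals_no_ti": (30.0, 200.0),
}


@dataclass(frozen=True)
class ExposureDesign:
    """Factorial layout of a cytotoxicity exposure experiment."""

    particles: tuple
    cell_lines: tuple = ("A549", "J774A.1")
    assays: tuple = ENDPOINTS
    doses: tuple = DEFAULT_DOSES
    n_experiments: int = 3
    n_technical: int = 2
    mechanistic_dose: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "cell_lines", tuple(self.cell_lines))
        object.__setattr__(self, "assays", tuple(self.assays))
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if not self.particles:
            raise DesignError("at least one particle required")
        if not set(self.assays) <= set(ENDPOINTS):
            raise DesignError(f"assays must be a subset of {ENDPOINTS}")
        if not self.doses or 0.0 not in self.doses:
            raise DesignError("dose series must be non-empty and include 0")
        if list(self.doses) != sorted(set(self.doses)):
            raise DesignError("doses must be strictly increasing")
        if any(d < 0 for d in self.doses):
            raise DesignError("doses must be non-negative")
        if self.n_experiments < 1 or self.n_technical < 1:
            raise DesignError("n_experiments and n_technical must be >= 1")
        if self.mechanistic_dose <= 0:
            raise DesignError("mechanistic_dose must be positive")


@dataclass
class PotencyTruth:
    """Ground-truth signed slopes and noise CV per particle x cell line x assay."""

    true_beta: Mapping[tuple, float]
    noise_cv: float = 0.1

    def __post_init__(self):
        if self.noise_cv < 0:
            raise DesignError("noise_cv must be >= 0")

    @classmethod
    def uniform(
        cls,
        design: ExposureDesign,
        beta_magnitude: "float | Mapping[str, float]" = 0.03,
        noise_cv: float = 0.1,
    ) -> "PotencyTruth":
        """Same |beta| everywhere, signed by assay directionality."""
        table = {}
        for p in design.particles:
            for cl in design.cell_lines:
                for a in design.assays:
                    mag = (
                        beta_magnitude[a]
                        if isinstance(beta_magnitude, Mapping)
                        else float(beta_magnitude)
                    )
                    table[(p, cl, a)] = ASSAY_SIGN[a] * mag
        return cls(true_beta=table, noise_cv=noise_cv)

    def slope(self, particle, cell_line, assay) -> float:
        return float(self.true_beta[(particle, cell_line, assay)])


#: Arbitrary-unit baselines per assay (scale cancels in fold effects).
_BASELINE = {"LDH": 100.0, "ATP": 1.0e5, "CTB": 5.0e4}


def generate_cytotox_plate(
    design: ExposureDesign,
    truth: PotencyTruth,
    seed: int,
    experiment_scale_sd: float = 0.05,
    cellfree_offset: "float | Mapping[tuple, float]" = 0.0,
    cellfree_blank: float = 1.0,
) -> pd.DataFrame:
    """Simulate plate-level raw signals for the full exposure design.

    ``signal = baseline * plate_scale * (dose+1)**slope * lognormal(cv)``.
    The experiment-level plate scale (lognormal, ``experiment_scale_sd``)
    cancels under dose-0 normalization.  One cell-free record per particle x
    assay x dose x experiment carries ``cellfree_blank`` plus the
    particle-interference ``cellfree_offset`` (scalar or keyed by
    (particle, dose)) so the correction path is exercisable.
    """
    if seed is None:
        raise DesignError("a seed is required")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + truth.noise_cv**2)))

    def offset(particle, dose) -> float:
        if isinstance(cellfree_offset, Mapping):
            return float(cellfree_offset.get((particle, dose), 0.0))
        return float(cellfree_offset)

    rows = []
    for particle in design.particles:
        for cl in design.cell_lines:
            for assay in design.assays:
                slope = truth.slope(particle, cl, assay)
                base = _BASELINE[assay]
                for exp in range(1, design.n_experiments + 1):
                    scale = (
                        float(np.exp(rng.normal(0.0, experiment_scale_sd)))
                        if experiment_scale_sd > 0
                        else 1.0
                    )
                    for dose in design.doses:
                        mean = base * scale * (dose + 1.0) ** slope
                        for tech in range(1, design.n_technical + 1):
                            noise = (
                                float(np.exp(rng.normal(0.0, sigma)))
                                if sigma > 0
                                else 1.0
                            )
                            rows.append(
                                (particle, cl, assay, dose, exp, tech, False,
                                 mean * noise)
                            )
                        rows.append(
                            (particle, cl, assay, dose, exp, 1, True,
                             cellfree_blank + offset(particle, dose))
                        )
    plate = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    if (plate["signal"] <= 0).any():
        raise GenerationError("generated non-positive signal; check offsets")
    return plate


def _planted_column(
    anchor: np.ndarray, target_r: float, rng: np.random.Generator,
    max_resamples: int = 100
) -> np.ndarray:
    """Standardized vector whose sample correlation with ``anchor`` is
    exactly ``target_r`` (built from an orthogonalized noise draw)."""
    if not -1.0 <= target_r <= 1.0:
        raise GenerationError("|target correlation| must be <= 1")
    n = len(anchor)
    if n < 3:
        raise GenerationError("need at least 3 rows to plant a correlation")
    sd = anchor.std()
    if sd <= max(abs(anchor.mean()), 1.0) * 1e-12:
        raise GenerationError("anchor vector is constant; correlation undefined")
    x = (anchor - anchor.mean()) / sd
    if abs(target_r) == 1.0:
        return np.sign(target_r) * x
    for _ in range(max_resamples):
        e = rng.normal(size=n)
        e = e - e.mean()
        e = e - x * (e @ x) / (x @ x)
        norm = np.sqrt((e**2).mean())
        if norm > 1e-12:
            return target_r * x + np.sqrt(1.0 - target_r**2) * (e / norm)
    raise GenerationError("could not draw a noise vector independent of anchor")


def _to_range(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Positive affine map onto [lo, hi]; preserves Pearson correlation."""
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        return np.full_like(z, (lo + hi) / 2.0)
    return lo + (z - zmin) / (zmax - zmin) * (hi - lo)


def generate_physchem_table(
    particles: Sequence[str],
    beta_avg: Sequence[float],
    planted_property: str = "bet_sa",
    target_r: float = 0.9,
    seed: int = 0,
    coatings: Sequence[str] | None = None,
    crystal_forms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-particle descriptor table with one planted correlated column.

    The ``planted_property`` column achieves sample correlation ``target_r``
    with ``beta_avg`` exactly (an affine transform at |target_r| = 1); all
    other descriptors are independent noise in plausible ranges.  Subset
    labels (``coating``, ``crystal_form``) default to "pristine"/"mixed" and
    are never inferred from particle names.
    """
    if planted_property not in _PHYSCHEM_RANGES:
        raise GenerationError(f"unknown property {planted_property!r}")
    particles = list(particles)
    beta = np.asarray(beta_avg, dtype=float)
    if len(particles) != len(beta):
        raise GenerationError("particles and beta_avg lengths differ")
    rng = np.random.default_rng(seed)

    table = {"particle": particles}
    for prop, (lo, hi) in _PHYSCHEM_RANGES.items():
        if prop == planted_property:
            z = _planted_column(beta, target_r, rng)
        else:
            z = rng.normal(size=len(particles))
        table[prop] = _to_range(z, lo, hi)
    df = pd.DataFrame(table)
    df["coating"] = list(coatings) if coatings is not None else "pristine"
    df["crystal_form"] = (
        list(crystal_forms) if crystal_forms is not None else "mixed"
    )

    got = np.corrcoef(df[planted_property], beta)[0, 1]
    if abs(got - target_r) > 0.05:
        raise GenerationError(
            f"planted correlation {got:.3f} misses target {target_r:.3f}"
        )
    return df


def generate_marker_panel(
    particles: Sequence[str],
    beta_avg: Sequence[float],
    target_r: float = -0.8,
    seed: int = 0,
    cell_line: str = "A549",
    mechanistic_dose: float = 30.0,
) -> pd.DataFrame:
    """Mechanistic marker fold changes at the single mechanistic dose.

    The GSH/GSSG-ratio fold change correlates with ``beta_avg`` at
    ``target_r`` (negative under oxidative stress); the cytokine fold change
    at ``-target_r``.  Both correlations are exact in-sample.
    """
    particles = list(particles)
    beta = np.asarray(beta_avg, dtype=float)
    if len(particles) != len(beta):
        raise GenerationError("particles and beta_avg lengths differ")
    rng = np.random.default_rng(seed)
    gsh = _to_range(_planted_column(beta, target_r, rng), 0.2, 1.2)
    cyt = _to_range(_planted_column(beta, -target_r, rng), 0.8, 6.0)
    return pd.DataFrame(
        {
            "particle": particles,
            "cell_line": cell_line,
            "dose": float(mechanistic_dose),
            "gsh_gssg_ratio_fc": gsh,
            "cytokine_fc": cyt,
        }
    )


def make_gene_sets(
    universe_size: int,
    n_sets: int = 10,
    set_size: int = 15,
    seed: int = 0,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random disjoint-draw gene sets over the synthetic protein universe."""
    if n_sets * 1 > universe_size or set_size >= universe_size:
        raise GenerationError("sets cannot exceed the universe")
    rng = np.random.default_rng(seed)
    ids = protein_ids(universe_size)
    sets = {}
    for s in range(n_sets):
        members = rng.choice(universe_size, size=set_size, replace=False)
        sets[f"{prefix}{s:03d}"] = frozenset(ids[m] for m in members)
    return GeneSetCollection(sets=sets)


def protein_ids(universe_size: int) -> list[str]:
    return [f"P{i:05d}" for i in range(universe_size)]


def generate_protein_matrix(
    universe_size: int,
    sets: GeneSetCollection,
    perturbed: Mapping[str, float],
    n_reps: int = 3,
    seed: int = 0,
    base_mean_log2: float = 7.0,
    base_sd_log2: float = 2.0,
    rep_sd_log2: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treated/control protein x replicate abundance matrices.

    Abundances are lognormal around a per-protein baseline; members of each
    perturbed set are shifted by the requested log2 effect in the treated
    samples only, every other protein is null.  Returns
    ``(treated, control)`` with protein ids in the index.
    """
    if n_reps < 2:
        raise GenerationError("n_reps must be >= 2")
    unknown = set(perturbed) - set(sets.sets)
    if unknown:
        raise GenerationError(f"perturbed names not in collection: {sorted(unknown)}")
    ids = protein_ids(universe_size)
    id_set = set(ids)
    for name in perturbed:
        extra = sets[name] - id_set
        if extra:
            raise GenerationError(
                f"set {name!r} references proteins outside the universe: "
                f"{sorted(extra)[:5]}"
            )
    rng = np.random.default_rng(seed)
    base = rng.normal(base_mean_log2, base_sd_log2, size=universe_size)

    effect = np.zeros(universe_size)
    index_of = {pid: i for i, pid in enumerate(ids)}
    for name, shift in perturbed.items():
        for pid in sets[name]:
            effect[index_of[pid]] += float(shift)

    control_log2 = base[:, None] + rng.normal(0, rep_sd_log2, (universe_size, n_reps))
    treated_log2 = (
        base[:, None]
        + effect[:, None]
        + rng.normal(0, rep_sd_log2, (universe_size, n_reps))
    )
    cols_t = [f"treated_{i+1}" for i in range(n_reps)]
    cols_c = [f"control_{i+1}" for i in range(n_reps)]
    treated = pd.DataFrame(2.0**treated_log2, index=ids, columns=cols_t)
    control = pd.DataFrame(2.0**control_log2, index=ids, columns=cols_c)
    treated.index.name = control.index.name = "protein"
    return treated, control
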