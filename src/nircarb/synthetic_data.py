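"""Synthetic NIR reflectance spectra with matching reference chemistry.

The generator emulates the statistical structure the calibration pipeline
assumes rather than any radiative-transfer physics:

* each constituent (starch, glucose, fructose, sucrose, plus water and a
  broad organic matrix as nuisance components) absorbs in Gaussian bands at
  its diagnostic NIR wavelengths;
* a sample's true absorbance is the Beer–Lambert mixture
  ``a(λ) = Σ_k c_k s_k(λ)``;
* each of the three replicate measurements distorts it with a
  multiplicative scatter factor, an affine baseline (offset + slope) and
  additive reflectance noise, then records ``R = 10**(-a)`` clipped to
  (0, 1].

The scatter/baseline artifacts are exactly the per-spectrum affine
distortions that SNV removes, so the generator exercises the preprocessing
chain in the way the real instrument artifacts would.

Default band positions follow the diagnostic regions for carbohydrates in
the 1100–2500 nm range: starch at 1480 / 1640 / 2020 / 2123 nm, free
sugars at 1150 / 1210 / 1748 / 2355 nm with component-distinct amplitude
ratios (so glucose, fructose and sucrose remain spectrally separable),
water at 1941 nm. The sugar-diagnostic region nominally starts near
1021 nm, below the grid; its in-grid portion is represented by the 1150
and 1210 nm bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from nircarb.chemistry import add_nsc_column
from nircarb.containers import (
    CONSTITUENTS,
    METADATA_COLUMNS,
    SpectraSet,
    check_grid,
)
from nircarb.errors import GridMismatchError, InvalidDesignError

N_REPLICATES = 3

TISSUES = (
    "trunk_phloem",
    "newly_branch",
    "one_yr_branch",
    "newly_needle",
    "one_yr_needle",
    "root",
)

#: Tissue groupings used by the separate-tissue calibration models: both
#: branch ages join the trunk phloem in the trunk group, both needle ages
#: form the needle group, and "mixed" pools everything.
TISSUE_GROUPS = {
    "trunk": ("trunk_phloem", "newly_branch", "one_yr_branch"),
    "root": ("root",),
    "needle": ("newly_needle", "one_yr_needle"),
    "mixed": TISSUES,
}


@dataclass(frozen=True)
class ComponentLibrary:
    """Gaussian absorption-band library on a fixed wavelength grid.

    ``bands[name]`` is a list of ``(center_nm, sigma_nm, amplitude)``
    triples; amplitude is absorbance per unit concentration (% dry mass
    for the carbohydrates and water, arbitrary units for the matrix).
    """

    component_names: tuple[str, ...]
    bands: dict[str, list[tuple[float, float, float]]]
    grid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", check_grid(self.grid))
        lo, hi = self.grid[0], self.grid[-1]
        for name in self.component_names:
            if name not in self.bands or not self.bands[name]:
                raise InvalidDesignError(f"component {name!r} has no bands")
            for center, sigma, amp in self.bands[name]:
                if sigma <= 0:
                    raise InvalidDesignError(f"{name}: band sigma must be > 0")
                if amp < 0:
                    raise InvalidDesignError(f"{name}: band amplitude must be >= 0")
                if not (lo - 3 * sigma <= center <= hi + 3 * sigma):
                    raise InvalidDesignError(
                        f"{name}: band at {center} nm lies outside the grid "
                        f"reach [{lo - 3 * sigma}, {hi + 3 * sigma}]"
                    )

    def component_spectrum(self, name: str) -> np.ndarray:
        """Unit-concentration absorbance spectrum of one component."""
        spectrum = np.zeros_like(self.grid)
        for center, sigma, amp in self.bands[name]:
            spectrum += amp * np.exp(-0.5 * ((self.grid - center) / sigma) ** 2)
        return spectrum

    def pure_spectra(self) -> np.ndarray:
        """Stack of unit spectra, shape (n_components, n_channels)."""
        return np.vstack([self.component_spectrum(n) for n in self.component_names])


def build_default_library(grid: np.ndarray) -> ComponentLibrary:
    """Default band library for the six mixture components.

    Bands whose centers would fall below the grid start (the sub-1100 nm
    part of the sugar region) are simply not included; all defaults lie
    inside the standard 1100–2500 nm grid.
    """
    grid = check_grid(grid)
    if grid.size < 2:
        raise InvalidDesignError("library grid needs >= 2 channels")
    span = grid[-1] - grid[0]
    bands = {
        "starch": [
            (1480.0, 18.0, 0.012),
            (1640.0, 20.0, 0.010),
            (2020.0, 16.0, 0.014),
            (2123.0, 16.0, 0.016),
        ],
        # shared sugar wavelengths, distinct amplitude ratios per sugar
        "glucose": [
            (1150.0, 20.0, 0.010),
            (1210.0, 20.0, 0.006),
            (1748.0, 14.0, 0.014),
            (2355.0, 16.0, 0.010),
        ],
        "fructose": [
            (1150.0, 20.0, 0.005),
            (1210.0, 20.0, 0.012),
            (1748.0, 14.0, 0.008),
            (2355.0, 16.0, 0.014),
        ],
        "sucrose": [
            (1150.0, 20.0, 0.008),
            (1210.0, 20.0, 0.008),
            (1748.0, 14.0, 0.012),
            (2355.0, 16.0, 0.006),
        ],
        "water": [(1941.0, 28.0, 0.008)],
        # broad organic backbone spanning the grid; per % dry mass, so the
        # ~80% structural fraction yields a ~1 AU baseline absorbance
        "matrix": [(grid[0] + span / 2, span / 2, 0.012)],
    }
    names = ("starch", "glucose", "fructose", "sucrose", "water", "matrix")
    return ComponentLibrary(component_names=names, bands=bands, grid=grid)


@dataclass(frozen=True)
class TissueDesign:
    """Concentration distribution of one tissue x season x treatment cell.

    Constituent concentrations are drawn from zero-truncated normals with
    the given means and sds (% dry mass). ``glucose_fructose_rho`` imposes
    a correlation between the glucose and fructose draws (strongly positive
    in trunk-like tissues); water and matrix are nuisance components drawn
    independently of the carbohydrates.
    """

    tissue: str
    season: str = "summer"
    treatment: str = "control"
    side: str = "not_applicable"
    n_samples: int = 100
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    water_mean: float = 5.0  # residual moisture after oven drying, % dry mass
    water_sd: float = 0.5
    matrix_mean: float = 80.0  # structural (cell-wall) fraction, % dry mass
    matrix_sd: float = 1.0
    glucose_fructose_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InvalidDesignError("n_samples must be >= 1")
        for const in CONSTITUENTS:
            if const not in self.means:
                raise InvalidDesignError(f"design lacks a mean for {const!r}")
            if self.means[const] < 0:
                raise InvalidDesignError(f"{const} mean must be >= 0")
            if self.sds.get(const, 0.0) < 0:
                raise InvalidDesignError(f"{const} sd must be >= 0")
        if self.water_sd < 0 or self.matrix_sd < 0:
            raise InvalidDesignError("nuisance sds must be >= 0")
        if not -1 < self.glucose_fructose_rho < 1:
            raise InvalidDesignError("glucose_fructose_rho must be in (-1, 1)")

    @property
    def label(self) -> str:
        return f"{self.tissue}_{self.season}_{self.treatment}_{self.side}"


def design(
    tissue: str,
    starch: float,
    glucose: float,
    fructose: float,
    sucrose: float,
    n_samples: int = 100,
    rel_sd: float = 0.15,
    **kwargs,
) -> TissueDesign:
    """Shorthand constructor: sds default to 15% of each mean."""
    means = {
        "starch": starch,
        "glucose": glucose,
        "fructose": fructose,
        "sucrose": sucrose,
    }
    sds = {k: rel_sd * v for k, v in means.items()}
    return TissueDesign(
        tissue=tissue, n_samples=n_samples, means=means, sds=sds, **kwargs
    )


def default_tissue_designs(n_samples: int = 100) -> dict[str, TissueDesign]:
    """Summer control-tree designs for the six sampled tissues.

    Trunk-phloem constituent means are the reported tissue maxima
    (starch 11.05, fructose 1.93, glucose 1.03, sucrose 0.63 % dry mass);
    one-year branch starch is 9.03 with total NSC near 9.68, and root
    starch is 9.64. Sucrose is set to trace level (<= 0.05%) in root and
    needle tissue, where only trace amounts occur. Remaining sugar means
    are realistic fill-ins; see the methods note.
    """
    return {
        "trunk_phloem": design(
            "trunk_phloem", 11.05, 1.03, 1.93, 0.63,
            n_samples=n_samples, glucose_fructose_rho=0.9,
        ),
        "newly_branch": design(
            "newly_branch", 6.0, 0.8, 1.2, 0.4,
            n_samples=n_samples, glucose_fructose_rho=0.8,
        ),
        "one_yr_branch": design(
            "one_yr_branch", 9.03, 0.25, 0.32, 0.08,
            n_samples=n_samples, glucose_fructose_rho=0.8,
        ),
        "newly_needle": design(
            "newly_needle", 4.0, 1.2, 1.5, 0.02, n_samples=n_samples
        ),
        "one_yr_needle": design(
            "one_yr_needle", 5.0, 1.0, 1.2, 0.02, n_samples=n_samples
        ),
        "root": design("root", 9.64, 0.25, 0.30, 0.01, n_samples=n_samples),
    }


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement artifacts and unmodelled sample chemistry.

    Replicate-level artifacts (scatter factor, affine baseline, additive
    reflectance noise) model the instrument; the structured background
    models sample-level biochemical variability the component library does
    not name: ``background_components`` fixed random band-comb spectra
    (Gaussian bands tiling the grid) whose per-sample loadings are drawn
    i.i.d. normal with sd ``background_sd`` (absorbance units). This is
    what gives every channel realistic y-independent variance; without it,
    synthetic spectra are unnaturally clean and every channel becomes
    informative about every constituent. Set every sd to 0 for exact
    Beer–Lambert spectra.
    """

    replicate_noise_sd: float = 0.0015  # additive, reflectance units
    baseline_offset_sd: float = 0.02  # absorbance units
    baseline_slope_sd: float = 2e-5  # absorbance per nm
    multiplicative_scatter_sd: float = 0.03  # dimensionless, around 1
    background_sd: float = 0.01  # absorbance units, per component loading
    background_components: int = 8
    background_band_spacing: float = 50.0  # nm between comb bands
    background_band_sigma: float = 22.0  # nm width of comb bands
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "replicate_noise_sd",
            "baseline_offset_sd",
            "baseline_slope_sd",
            "multiplicative_scatter_sd",
            "background_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")
        if self.background_components < 0:
            raise InvalidDesignError("background_components must be >= 0")

    def silent(self) -> "NoiseConfig":
        """Copy with every artifact sd set to zero (same seed)."""
        return replace(
            self,
            replicate_noise_sd=0.0,
            baseline_offset_sd=0.0,
            baseline_slope_sd=0.0,
            multiplicative_scatter_sd=0.0,
            background_sd=0.0,
        )


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _correlated_truncated_pair(
    mean1: float, sd1: float, mean2: float, sd2: float,
    rho: float, size: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal with correlation rho, redrawn until non-negative."""
    if sd1 == 0 and sd2 == 0:
        return np.full(size, mean1), np.full(size, mean2)
    out1 = np.empty(size)
    out2 = np.empty(size)
    need = np.arange(size)
    while need.size:
        z1 = rng.standard_normal(need.size)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(need.size)
        x1 = mean1 + sd1 * z1
        x2 = mean2 + sd2 * z2
        ok = (x1 >= 0) & (x2 >= 0)
        out1[need[ok]] = x1[ok]
        out2[need[ok]] = x2[ok]
        need = need[~ok]
    return out1, out2


def sample_concentrations(
    design: TissueDesign, rng_seed: int
) -> pd.DataFrame:
    """Draw a reference-chemistry table for one design.

    Concentrations are zero-truncated normals; the NSC column is computed
    as the constituent sum, never drawn. Columns follow the chemistry-table
    contract plus hidden ``water`` and ``matrix`` nuisance columns used by
    the spectral forward model.
    """
    rng = np.random.default_rng(rng_seed)
    n = design.n_samples
    rho = design.glucose_fructose_rho
    if rho != 0:
        glucose, fructose = _correlated_truncated_pair(
            design.means["glucose"], design.sds.get("glucose", 0.0),
            design.means["fructose"], design.sds.get("fructose", 0.0),
            rho, n, rng,
        )
    else:
        glucose = _truncated_normal(
            design.means["glucose"], design.sds.get("glucose", 0.0), n, rng
        )
        fructose = _truncated_normal(
            design.means["fructose"], design.sds.get("fructose", 0.0), n, rng
        )
    sucrose = _truncated_normal(
        design.means["sucrose"], design.sds.get("sucrose", 0.0), n, rng
    )
    starch = _truncated_normal(
        design.means["starch"], design.sds.get("starch", 0.0), n, rng
    )
    water = _truncated_normal(design.water_mean, design.water_sd, n, rng)
    matrix = _truncated_normal(design.matrix_mean, design.matrix_sd, n, rng)
    table = pd.DataFrame(
        {
            "sample_id": [f"{design.label}_{i:04d}" for i in range(n)],
            "tissue": design.tissue,
            "season": design.season,
            "treatment": design.treatment,
            "side": design.side,
            "glucose": glucose,
            "fructose": fructose,
            "sucrose": sucrose,
            "starch": starch,
            "water": water,
            "matrix": matrix,
        }
    )
    return add_nsc_column(table)


def mixture_absorbance(
    library: ComponentLibrary, concentrations: dict[str, float] | pd.Series
) -> np.ndarray:
    """Noise-free Beer–Lambert absorbance of one mixture on the grid."""
    a = np.zeros_like(library.grid)
    for name in library.component_names:
        c = float(concentrations.get(name, 0.0))
        if c:
            a += c * library.component_spectrum(name)
    return a


def background_basis(
    grid: np.ndarray, noise: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Fixed band-comb spectra for the structured background.

    Each of the ``background_components`` spectra is a comb of Gaussian
    bands (spacing jittered around ``background_band_spacing``) normalized
    to unit standard deviation over the grid, so ``background_sd`` is the
    absorbance scale of each component's per-sample loading.
    """
    spacing = noise.background_band_spacing
    sigma = noise.background_band_sigma
    basis = []
    for _ in range(noise.background_components):
        centers = np.arange(grid[0] - spacing, grid[-1] + spacing, spacing)
        centers = centers + rng.uniform(-spacing / 2, spacing / 2, centers.size)
        amps = rng.normal(0.0, 1.0, centers.size)
        g = np.zeros_like(grid)
        for a, c in zip(amps, centers):
            g += a * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
        sd = g.std()
        basis.append(g / sd if sd > 0 else g)
    return np.array(basis) if basis else np.zeros((0, grid.size))


def generate_dataset(
    designs: list[TissueDesign],
    library: ComponentLibrary,
    noise: NoiseConfig,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Generate replicate reflectance spectra plus reference chemistry.

    Each sample's true absorbance is the Beer–Lambert mixture plus its
    structured-background contribution; every sample then gets
    :data:`N_REPLICATES` replicate spectra, replicate r recording
    ``R = 10**(-(m*a + offset + slope*(λ-λ_mid))) + ε`` with its own
    scatter factor m ~ N(1, scatter_sd), baseline offset and slope, and
    additive reflectance noise ε. Fully reproducible from ``noise.seed``.
    """
    if not designs:
        raise InvalidDesignError("need at least one design")
    root_seq = np.random.SeedSequence(noise.seed)
    conc_seeds, noise_seed = root_seq.spawn(2)
    rng = np.random.default_rng(noise_seed)

    tables = []
    for i, dsg in enumerate(designs):
        child = np.random.SeedSequence(entropy=conc_seeds.entropy,
                                       spawn_key=conc_seeds.spawn_key + (i,))
        tables.append(sample_concentrations(dsg, child))
    chem = pd.concat(tables, ignore_index=True)
    if chem["sample_id"].duplicated().any():
        raise InvalidDesignError(
            "duplicate sample ids: give designs distinct tissue/season/"
            "treatment/side labels"
        )

    grid = library.grid
    lam_mid = 0.5 * (grid[0] + grid[-1])
    pure = library.pure_spectra()
    conc = chem[list(library.component_names)].to_numpy(dtype=float)
    true_absorbance = conc @ pure  # (n_samples, n_channels)
    if noise.background_sd > 0 and noise.background_components > 0:
        basis = background_basis(grid, noise, rng)
        loadings = rng.normal(0.0, noise.background_sd, (len(chem), basis.shape[0]))
        true_absorbance = true_absorbance + loadings @ basis

    n_samples = len(chem)
    n_rows = n_samples * N_REPLICATES
    reflectance = np.empty((n_rows, grid.size))
    sample_id = np.empty(n_rows, dtype=object)
    replicate = np.empty(n_rows, dtype=int)
    row = 0
    for i in range(n_samples):
        for r in range(N_REPLICATES):
            m = 1.0 + noise.multiplicative_scatter_sd * rng.standard_normal()
            offset = noise.baseline_offset_sd * rng.standard_normal()
            slope = noise.baseline_slope_sd * rng.standard_normal()
            a = m * true_absorbance[i] + offset + slope * (grid - lam_mid)
            r_spec = np.power(10.0, -a)
            if noise.replicate_noise_sd:
                r_spec = r_spec + noise.replicate_noise_sd * rng.standard_normal(
                    grid.size
                )
            reflectance[row] = np.clip(r_spec, 1e-8, 1.0)
            sample_id[row] = chem["sample_id"].iloc[i]
            replicate[row] = r
            row += 1

    metadata = (
        chem[["sample_id", *METADATA_COLUMNS]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    spectra = SpectraSet(
        grid=grid,
        reflectance=reflectance,
        sample_id=sample_id,
        replicate=replicate,
        metadata=metadata,
    )
    return spectra, chem


def root_like_design(n_samples: int = 300) -> TissueDesign:
    """The root-tissue calibration scenario used for benchmark runs.

    Root tissue has the strongest starch signal relative to its sugar
    content (starch mean 9.64% dry mass, trace sucrose), which is what
    makes it the best-predicted tissue; n defaults to 300 samples.
    """
    return design("root", 9.64, 0.25, 0.30, 0.01, n_samples=n_samples)


def single_constituent_design(
    target: str = "starch", n_samples: int = 60,
    mean: float = 10.0, sd: float = 1.5,
) -> TissueDesign:
    """A spectrally isolated single-analyte scenario for selection tests.

    Only the target constituent is present (the others at zero
    concentration, so they contribute no absorption bands); residual
    moisture is absent and the structural backbone is held constant. The
    only y-independent variance then comes from the noise model's
    structured background and replicate artifacts, which is the cleanest
    setting in which to ask whether variable selection recovers the
    target's true band positions.
    """
    if target not in CONSTITUENTS:
        raise InvalidDesignError(f"unknown constituent {target!r}")
    means = {c: 0.0 for c in CONSTITUENTS}
    sds = {c: 0.0 for c in CONSTITUENTS}
    means[target] = mean
    sds[target] = sd
    return TissueDesign(
        tissue="root",
        n_samples=n_samples,
        means=means,
        sds=sds,
        water_mean=0.0,
        water_sd=0.0,
        matrix_mean=80.0,
        matrix_sd=0.0,
    )


def root_like_scenario(
    n_samples: int = 300, seed: int = 0
) -> tuple[list[TissueDesign], NoiseConfig]:
    """Designs + noise for the root-tissue calibration benchmark.

    Uses the default noise model (8 background components at 0.01 AU):
    moderate masking, under which the starch calibration is strong and
    variable selection retains a modest fraction of the channels.
    """
    return [root_like_design(n_samples)], NoiseConfig(seed=seed)


def selection_fidelity_scenario(
    target: str = "starch", n_samples: int = 60, seed: int = 0
) -> tuple[list[TissueDesign], NoiseConfig]:
    """Designs + noise for the band-recovery benchmark.

    Pairs the spectrally isolated single-analyte design with a richer
    structured background (16 components): with the analyte as the only
    named varying constituent, the dense background is what masks the
    incidental normalization-induced correlations at off-band channels, so
    the channels that survive selection are the ones carrying direct band
    information.
    """
    return (
        [single_constituent_design(target, n_samples=n_samples)],
        NoiseConfig(seed=seed, background_components=16),
    )


def group_sample_ids(chem: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to one calibration group (trunk/root/needle/mixed)."""
    if group not in TISSUE_GROUPS:
        raise InvalidDesignError(
            f"unknown group {group!r}; choose from {sorted(TISSUE_GROUPS)}"
        )
    tissues = TISSUE_GROUPS[group]
    mask = chem["tissue"].isin(tissues)
    return chem.loc[mask, "sample_id"].tolist()
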