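"""Synthetic lipogenesis experiments with full ground truth.

The generator emulates a microtiter-plate screening study: three oleaginous
fungal species cultivated at two temperatures for twelve days, three
biological replicates each measured in three technical FTIR replicates
(3 x 2 x 12 x 3 x 3 = 648 raw spectra over 216 biological samples), with a
matched GC fatty-acid table (one composition per species/temperature/day
condition, as GC is run on pooled biomass) and a glucose-consumption table.

Spectra are Beer-Lambert mixtures of Gaussian-band pure-component spectra
(lipid, protein, carbohydrate, polyphosphate).  Over the cultivation the
lipid fraction L(day) rises along a logistic curve while the non-lipid
fraction shrinks, reproducing the growth of ester-carbonyl / acyl-chain
bands at the expense of the amide bands.  The fatty-acid composition
interpolates from a PUFA-rich growth-phase profile to a MUFA-rich
stationary-phase profile around the growth-to-stationary transition day;
species differ in which C18 triene they make (n-6 gamma-linolenic for the
Mucoromycota-type species, n-3 alpha-linolenic for the Penicillium-type
one).  The olefinic =C-H band inside the lipid component moves linearly
with the unsaturation index through the anchor points (UI 0.93, 3006 cm^-1)
and (UI 1.43, 3012 cm^-1), and its amplitude grows with UI.

Measurement artifacts per technical replicate: multiplicative path-length
scatter b, additive offset a, linear/quadratic baseline (c, d) on the
[-1, 1]-mapped wavenumber axis, and white noise.  All draws come from one
seeded generator; identical seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FtirlipError
from .fatty_acids import FattyAcidTable
from .spectra import SampleMeta, SpectrumSet

# UI -> olefinic band position anchors (cm^-1 per UI unit slope ~ 12)
_UI_LO, _POS_LO = 0.93, 3006.0
_UI_HI, _POS_HI = 1.43, 3012.0


def olefinic_center(ui: float, slope: Optional[float] = None) -> float:
    """Olefinic =C-H band center as a linear function of unsaturation index,
    through (0.93, 3006 cm^-1) and (1.43, 3012 cm^-1)."""
    s = (_POS_HI - _POS_LO) / (_UI_HI - _UI_LO) if slope is None else slope
    return _POS_LO + s * (ui - _UI_LO)


def _gauss(grid: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


# (center cm^-1, sigma cm^-1, relative amplitude)
_LIPID_BANDS = [
    (2955.0, 10.0, 0.55),  # CH3 asym stretch
    (2925.0, 11.0, 0.90),  # CH2 asym stretch
    (2850.0, 10.0, 0.60),  # CH2 sym stretch
    (1745.0, 10.0, 1.00),  # C=O ester stretch
    (1465.0, 10.0, 0.35),  # CH2 scissoring
    (725.0, 9.0, 0.12),  # CH2 rocking
]
#: =C-H stretch centers of mono-, di- and triunsaturated acyl chains; the
#: aggregate band maximum then moves with the unsaturation index.  The two
#: triene isomers differ slightly: the terminal double bond of the n-3
#: isomer sits higher in wavenumber than the n-6 one.
_OLEFINIC_CLASS_CENTERS = (3004.0, 3008.0, 3012.0)
_TRIENE_CENTER_N6 = 3011.0
_TRIENE_CENTER_N3 = 3014.0
_PROTEIN_BANDS = [(1650.0, 18.0, 1.00), (1540.0, 16.0, 0.70)]  # amide I, II
_CARB_BANDS = [(1150.0, 12.0, 0.50), (1080.0, 14.0, 1.00), (1033.0, 12.0, 0.85)]
_POLYP_BANDS = [(1260.0, 14.0, 0.80), (880.0, 10.0, 0.50)]


def generate_pure_component_spectra(
    grid: np.ndarray, ui: float = 1.1
) -> Dict[str, np.ndarray]:
    """Pure-component spectra {lipid, protein, carbohydrate, polyphosphate}.

    Each component is a sum of Gaussian bands at the literature positions,
    max-normalized to 1.  The lipid component includes the UI-dependent
    olefinic band: center from :func:`olefinic_center`, amplitude growing
    linearly with UI (more double bonds, more =C-H oscillators).
    """
    grid = np.asarray(grid, float)
    lo, hi = grid.min(), grid.max()
    if lo > 725.0 or hi < 3020.0:
        raise FtirlipError(
            f"grid [{lo:g}, {hi:g}] cm^-1 does not cover the component bands"
        )

    def build(bands):
        out = np.zeros_like(grid)
        for c, s, a in bands:
            out += _gauss(grid, c, s, a)
        return out / out.max()

    lipid_bands = _LIPID_BANDS + [(olefinic_center(ui), 8.0, 0.10 + 0.25 * ui)]
    return {
        "lipid": build(lipid_bands),
        "protein": build(_PROTEIN_BANDS),
        "carbohydrate": build(_CARB_BANDS),
        "polyphosphate": build(_POLYP_BANDS),
    }


def _lipid_component(
    grid: np.ndarray, mono: float, diene: float, triene: float, triene_omega: str = "n6"
) -> np.ndarray:
    """Lipid pure-component spectrum for a given unsaturation-class split
    (percentages of total fatty acids).  The olefinic region is the
    superposition of one =C-H sub-band per double-bond class, each weighted
    by its number of =C-H oscillators (class double bonds x class fraction),
    so the aggregate peak drifts up in wavenumber as unsaturation grows.
    ``triene_omega`` selects the n-3 or n-6 triene sub-band center."""
    out = np.zeros_like(grid)
    for c, s, a in _LIPID_BANDS:
        out += _gauss(grid, c, s, a)
    tri_center = _TRIENE_CENTER_N3 if triene_omega == "n3" else _TRIENE_CENTER_N6
    centers = (_OLEFINIC_CLASS_CENTERS[0], _OLEFINIC_CLASS_CENTERS[1], tri_center)
    for center, db, pct in zip(centers, (1, 2, 3), (mono, diene, triene)):
        out += _gauss(grid, center, 8.0, 0.10 / 3.0 + 0.25 * db * pct / 100.0)
    return out / out.max()


# ---------------------------------------------------------------------------
# Study-design configuration

# growth-phase (PUFA-rich) and stationary-phase (MUFA-rich) composition
# vectors, % of total fatty acids; each sums to 100.
_ACIDS_N6 = ["C14:0", "C16:0", "C16:1", "C18:0", "C18:1n9", "C18:2n6", "C18:3n6"]
_ACIDS_N3 = ["C14:0", "C16:0", "C16:1", "C18:0", "C18:1n9", "C18:2n6", "C18:3n3"]


@dataclass
class SpeciesProfile:
    name: str
    acids: List[str]
    start_composition: np.ndarray  # growth phase, PUFA-rich
    end_composition: np.ndarray  # stationary phase, MUFA-rich
    lipid_plateau: Dict[float, float]  # temperature -> plateau, % of CDW
    glucose_end: Dict[float, float]  # temperature -> residual glucose, g/L
    #: cell-wall polyphosphate weight in the non-lipid mix, start -> end of
    #: cultivation (species-specific: strong in M. circinelloides)
    polyphosphate: Tuple[float, float] = (0.04, 0.10)


def _default_species() -> List[SpeciesProfile]:
    return [
        SpeciesProfile(
            name="M_circinelloides",
            acids=list(_ACIDS_N6),
            start_composition=np.array([2.0, 22.0, 2.0, 4.0, 26.0, 30.0, 14.0]),
            end_composition=np.array([2.0, 24.0, 2.0, 7.0, 43.0, 16.0, 6.0]),
            lipid_plateau={20.0: 31.0, 30.0: 35.0},
            glucose_end={20.0: 45.0, 30.0: 3.0},
            polyphosphate=(0.05, 0.22),
        ),
        SpeciesProfile(
            name="U_isabellina",
            acids=list(_ACIDS_N6),
            start_composition=np.array([1.5, 20.0, 2.5, 3.0, 30.0, 29.0, 14.0]),
            end_composition=np.array([1.5, 22.0, 2.5, 5.0, 46.0, 17.0, 6.0]),
            lipid_plateau={20.0: 37.0, 30.0: 33.0},
            glucose_end={20.0: 6.0, 30.0: 2.0},
            polyphosphate=(0.04, 0.12),
        ),
        SpeciesProfile(
            name="P_glabrum",
            acids=list(_ACIDS_N3),
            start_composition=np.array([1.0, 19.0, 1.5, 4.5, 22.0, 36.0, 16.0]),
            end_composition=np.array([1.0, 23.0, 1.5, 7.5, 37.0, 23.0, 7.0]),
            lipid_plateau={20.0: 26.0, 30.0: 28.0},
            glucose_end={20.0: 8.0, 30.0: 5.0},
            polyphosphate=(0.03, 0.05),
        ),
    ]


#: Early-growth condition-days conventionally excluded before calibration:
#: biomass measured before lipogenesis has begun does not follow the
#: lipid-dominated spectrum-composition relationship.
EARLY_GROWTH_EXCLUSIONS = (
    ("M_circinelloides", 20.0, 1),
    ("P_glabrum", 20.0, 2),
    ("P_glabrum", 30.0, 1),
)

#: Drop list reproducing a 210-biological-sample design (the full factorial
#: grid holds 216 cells; six late-day U. isabellina 30 C replicate cells are
#: removed to emulate incomplete sampling).
STUDY_210_DROP = tuple(
    ("U_isabellina", 30.0, day, bio) for day in (11, 12) for bio in (1, 2, 3)
)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic screening experiment.

    Defaults reproduce the reference design: 3 species x 2 temperatures x
    12 days x 3 biological x 3 technical replicates.  Noise terms: additive
    spectral noise SD in absorbance units, multiplicative scatter b drawn
    uniformly from ``b_range`` per technical replicate, baseline
    coefficients uniform in ``+/- baseline_scale``, glucose replicate noise
    SD in g/L, and a Dirichlet concentration controlling composition jitter
    between condition days (None disables jitter).
    """

    species: List[SpeciesProfile] = field(default_factory=_default_species)
    temperatures: Tuple[float, ...] = (20.0, 30.0)
    days: Tuple[int, ...] = tuple(range(1, 13))
    bio_reps: int = 3
    tech_reps: int = 3
    grid_max: float = 4000.0
    grid_min: float = 500.0
    grid_step: float = 6.0
    # noise / artifact model
    noise_sd: float = 0.002  # additive white noise, absorbance units
    b_range: Tuple[float, float] = (0.7, 1.3)
    offset_sd: float = 0.02
    baseline_scale: float = 0.05
    bio_amplitude_sd: float = 0.03  # lognormal sigma of per-bio-rep amplitude
    #: Dirichlet concentration for day-to-day composition jitter; 4000 puts
    #: the relative SD of the dominant acid near 2%, the reproducibility
    #: level of replicated GC composition measurements.  None = exact.
    composition_concentration: Optional[float] = 4000.0
    glucose_noise_sd: float = 1.1  # g/L, replicate-level
    # kinetics
    lipid_start: float = 6.0  # % of CDW at inoculation
    lipid_rate: float = 1.2  # logistic steepness, 1/day
    lipid_onset: Dict[float, float] = field(
        default_factory=lambda: {20.0: 4.5, 30.0: 3.0}
    )
    #: the PUFA->MUFA composition shift and lipid accumulation are both
    #: triggered by nitrogen depletion, so they share one clock by default
    composition_transition: Dict[float, float] = field(
        default_factory=lambda: {20.0: 4.5, 30.0: 3.0}
    )
    composition_width: float = 1.0 / 1.2  # days; matches the lipid logistic rate
    glucose_start: float = 80.0  # g/L in the medium
    glucose_rate: float = 0.9
    amplitude: float = 0.8  # overall absorbance scale of a dried film
    #: at 30 C shift this much composition from the triene to the diene in
    #: the stationary profile (linoleic higher at 30 C, triene at 20 C)
    warm_diene_shift: float = 4.0
    drop_conditions: Tuple[Tuple[str, float, int, int], ...] = ()
    seed: int = 2017

    def __post_init__(self):
        for sp in self.species:
            for v in (sp.start_composition, sp.end_composition):
                if abs(v.sum() - 100.0) > 1e-9:
                    raise FtirlipError(f"{sp.name}: composition must sum to 100")
            if any(p > 70.0 for p in sp.lipid_plateau.values()):
                raise FtirlipError(
                    f"{sp.name}: lipid plateau above the 70% biological ceiling"
                )

    @classmethod
    def noise_free(cls, **overrides) -> "SyntheticConfig":
        """All stochastic terms off: b = 1, no baseline, no jitter."""
        base = dict(
            noise_sd=0.0,
            b_range=(1.0, 1.0),
            offset_sd=0.0,
            baseline_scale=0.0,
            bio_amplitude_sd=0.0,
            composition_concentration=None,
            glucose_noise_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticExperiment:
    spectra: SpectrumSet  # raw technical-replicate spectra
    fatty_acids: FattyAcidTable  # one row per (species, temperature, day)
    glucose: pd.DataFrame  # species, temperature, day, bio_rep, glucose_g_l
    truth: pd.DataFrame  # per raw spectrum: lipid %, UI, scatter coefficients
    truth_composition: pd.DataFrame  # condition-level exact composition
    config: SyntheticConfig = None


def _logistic(x, lo, hi, rate, onset):
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (x - onset)))


def generate_experiment(
    cfg: SyntheticConfig = None, seed: Optional[int] = None
) -> SyntheticExperiment:
    """Generate one full synthetic screening experiment.

    Deterministic given (cfg, seed): identical inputs give bitwise-identical
    outputs.  ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    n_pts = int(np.floor((cfg.grid_max - cfg.grid_min) / cfg.grid_step)) + 1
    grid = cfg.grid_max - cfg.grid_step * np.arange(n_pts)
    t_axis = 2.0 * (grid - grid.min()) / (grid.max() - grid.min()) - 1.0
    base_components = generate_pure_component_spectra(grid)

    dropped = set(cfg.drop_conditions)
    spectra_rows: List[np.ndarray] = []
    meta: List[SampleMeta] = []
    truth_rows: List[dict] = []
    fa_rows: List[dict] = []
    glucose_rows: List[dict] = []

    for sp in cfg.species:
        for temp in cfg.temperatures:
            plateau = sp.lipid_plateau[temp]
            end_comp = sp.end_composition.copy()
            if temp >= 25.0:  # warmer: more diene, less triene in stationary oil
                end_comp[-1] -= cfg.warm_diene_shift
                end_comp[-2] += cfg.warm_diene_shift
            t_trans = cfg.composition_transition[temp]
            onset = cfg.lipid_onset[temp]
            for day in cfg.days:
                # condition-level truth ------------------------------------
                lipid_pct = _logistic(day, cfg.lipid_start, plateau, cfg.lipid_rate, onset)
                s = 1.0 / (1.0 + np.exp(-(day - t_trans) / cfg.composition_width))
                comp = sp.start_composition + s * (end_comp - sp.start_composition)
                if cfg.composition_concentration is not None:
                    comp = 100.0 * rng.dirichlet(
                        comp / 100.0 * cfg.composition_concentration
                    )
                db = np.array(
                    [0, 0, 1, 0, 1, 2, 3], float
                )  # double bonds per acid in profile order
                ui = float(comp @ db / 100.0)

                fa_row = {
                    "species": sp.name,
                    "temperature": temp,
                    "day": day,
                    **{a: float(c) for a, c in zip(sp.acids, comp)},
                    "total_lipid": float(lipid_pct),
                }
                fa_rows.append(fa_row)

                lipid_component = _lipid_component(
                    grid, mono=float(comp[2] + comp[4]), diene=float(comp[5]),
                    triene=float(comp[6]),
                    triene_omega="n3" if sp.acids[-1].endswith("n3") else "n6",
                )
                # the non-lipid mix drifts with cultivation time: cell-wall
                # glucan (carbohydrate) and polyphosphate bands grow at the
                # expense of protein, most strongly in M. circinelloides
                u = (day - cfg.days[0]) / max(cfg.days[-1] - cfg.days[0], 1)
                w_pp = sp.polyphosphate[0] + u * (sp.polyphosphate[1] - sp.polyphosphate[0])
                w_carb = 0.30 + 0.10 * u
                nonlipid = (
                    (1.0 - w_carb - w_pp) * base_components["protein"]
                    + w_carb * base_components["carbohydrate"]
                    + w_pp * base_components["polyphosphate"]
                )
                mixture_base = (
                    lipid_pct / 100.0 * lipid_component
                    + (1.0 - lipid_pct / 100.0) * nonlipid
                )

                glucose_true = cfg.glucose_start - _logistic(
                    day, 0.0, cfg.glucose_start - sp.glucose_end[temp],
                    cfg.glucose_rate, onset,
                )

                for bio in range(1, cfg.bio_reps + 1):
                    if (sp.name, temp, day, bio) in dropped:
                        continue
                    amp = cfg.amplitude * (
                        np.exp(rng.normal(0.0, cfg.bio_amplitude_sd))
                        if cfg.bio_amplitude_sd > 0
                        else 1.0
                    )
                    clean = amp * mixture_base
                    g_obs = glucose_true + (
                        rng.normal(0.0, cfg.glucose_noise_sd)
                        if cfg.glucose_noise_sd > 0
                        else 0.0
                    )
                    glucose_rows.append(
                        {
                            "species": sp.name,
                            "temperature": temp,
                            "day": day,
                            "bio_rep": bio,
                            "glucose_g_l": max(float(g_obs), 0.0),
                            "glucose_true": float(glucose_true),
                        }
                    )
                    for tech in range(1, cfg.tech_reps + 1):
                        b = rng.uniform(*cfg.b_range)
                        a = rng.normal(0.0, cfg.offset_sd) if cfg.offset_sd > 0 else 0.0
                        c = rng.uniform(-cfg.baseline_scale, cfg.baseline_scale)
                        d = rng.uniform(-cfg.baseline_scale, cfg.baseline_scale)
                        noise = (
                            rng.normal(0.0, cfg.noise_sd, size=n_pts)
                            if cfg.noise_sd > 0
                            else 0.0
                        )
                        row = b * clean + a + c * t_axis + d * t_axis**2 + noise
                        sid = f"{sp.name}_{temp:g}C_d{day:02d}_b{bio}_t{tech}"
                        spectra_rows.append(row)
                        meta.append(
                            SampleMeta(
                                sample_id=sid,
                                species=sp.name,
                                temperature=temp,
                                day=day,
                                bio_rep=bio,
                                tech_rep=tech,
                            )
                        )
                        truth_rows.append(
                            {
                                "sample_id": sid,
                                "species": sp.name,
                                "temperature": temp,
                                "day": day,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "lipid_pct": float(lipid_pct),
                                "unsaturation_index": ui,
                                "amplitude": float(amp),
                                "a": float(a),
                                "b": float(b),
                                "c": float(c),
                                "d": float(d),
                                "glucose_true": float(glucose_true),
                            }
                        )

    spectra = SpectrumSet(grid, np.array(spectra_rows), meta)
    fa_df = pd.DataFrame(fa_rows).fillna(0.0)
    # unify columns across species (n3 vs n6 triene producers)
    acid_cols = sorted(
        {c for c in fa_df.columns if c not in ("species", "temperature", "day", "total_lipid")}
    )
    fa_df = fa_df[["species", "temperature", "day"] + acid_cols + ["total_lipid"]]
    fatty_acids = FattyAcidTable(fa_df)
    truth = pd.DataFrame(truth_rows)
    truth_composition = fa_df.copy()
    return SyntheticExperiment(
        spectra=spectra,
        fatty_acids=fatty_acids,
        glucose=pd.DataFrame(glucose_rows),
        truth=truth,
        truth_composition=truth_composition,
        config=cfg,
    )


def generate_fold_fixture(
    n_samples: int,
    n_vars: int,
    beta: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Small linear-regression fixture: X ~ N(0,1), y = X beta + eps."""
    if not n_samples > n_vars >= 1:
        raise ValueError("need n_samples > n_vars >= 1")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_vars))
    beta = rng.standard_normal(n_vars) if beta is None else np.asarray(beta, float)
    eps = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else np.zeros(n_samples)
    y = X @ beta + eps
    return X, y, {"beta": beta, "noise_sd": noise_sd, "eps": eps}
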