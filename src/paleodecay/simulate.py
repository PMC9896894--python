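"""Synthetic multiproxy sediment cores and community tables.

The generator reproduces the statistical structure the analysis assumes:

* monotone age-depth structure (constant sedimentation rate per core),
* per-analyte power-law decay Y_i = a * t_i**b * exp(eps_i) with
  multiplicative lognormal measurement noise eps_i ~ N(0, sigma^2),
* Dirichlet-multinomial amplicon read counts whose group proportions
  drift with age because each group's underlying intensity follows its
  own power decay, and
* lognormal noise on qPCR total copy numbers.

The "paper-like" preset encodes group decay constants near values
reported for Swiss lake cores (diatom DNA k ~ 1.6, green algal DNA
k ~ 0.7, vascular plant DNA k ~ 0.1, lipid biomarkers k ~ 0.45-0.6);
these are calibration inputs for testing the pipeline, not ground truth
about any particular lake.  Depth/age presets echo ~40 cm cores spanning
~180 years, with a ~600-year variant.

Everything is driven by one seeded ``numpy.random.Generator``; identical
spec + seed gives byte-identical CSV bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import AnalyteSeries
from .agemodel import AgeModel

DEFAULT_SIGMA_LOG = 0.3  # lognormal SD of measurement noise, log_e units


@dataclass
class AnalyteSpec:
    """Generative parameters of one analyte: Y = amplitude * t**exponent."""

    analyte_id: str
    amplitude: float
    exponent: float  # b <= 0 for decay
    sigma_log: float = DEFAULT_SIGMA_LOG
    organism_group: str = "other"
    compound_class: str = "other"
    units: str = "arb. units g-1 dry sediment"
    #: restrict to the deepest station (biomarkers/macromolecules are
    #: typically measured only there)
    deepest_station_only: bool = False

    def __post_init__(self):
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


@dataclass
class CommunitySpec:
    """Generative parameters of the amplicon table + qPCR totals.

    Per-sample group intensities are I_g(t) = amplitude_g * t**(-k_g)
    (copies per g dry sediment); the total copy number is their sum times
    lognormal noise, and read counts are Dirichlet-multinomial around the
    group proportions I_g / sum(I).  ``dirichlet_concentration=None``
    disables the Dirichlet overdispersion (proportions used exactly);
    ``multinomial_sampling=False`` additionally replaces the multinomial
    draw by largest-remainder rounding so read fractions equal the exact
    proportions up to 1/read_depth.
    """

    group_amplitudes: dict = field(default_factory=lambda: {
        "diatom": 6e8, "green_alga": 1e8, "vascular_plant": 5e6, "other": 3e8})
    group_decay: dict = field(default_factory=lambda: {
        "diatom": 1.82, "green_alga": 0.57, "vascular_plant": 0.22, "other": 0.5})
    read_depth: int = 50_000
    dirichlet_concentration: float | None = 200.0
    total_sigma_log: float = 0.2
    taxa_per_group: int = 3
    multinomial_sampling: bool = True

    def __post_init__(self):
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if set(self.group_amplitudes) != set(self.group_decay):
            raise ValueError("group_amplitudes and group_decay must share keys")


def _default_analytes() -> list[AnalyteSpec]:
    copies = "gene copies g-1 dry sediment"
    ug = "ug g-1 dry sediment"
    return [
        AnalyteSpec("diatom_rbcL", 1e9, -1.57, organism_group="diatom",
                    compound_class="DNA", units=copies),
        AnalyteSpec("green_alga_rbcL", 1e8, -0.70, organism_group="green_alga",
                    compound_class="DNA", units=copies),
        AnalyteSpec("vascular_plant_rbcL", 1e6, -0.12,
                    organism_group="vascular_plant", compound_class="DNA",
                    units=copies),
        AnalyteSpec("fatty_acid_C20:5n-3", 50.0, -0.52, organism_group="diatom",
                    compound_class="fatty_acid", units=ug,
                    deepest_station_only=True),
        AnalyteSpec("diatom_sterols", 30.0, -0.61, organism_group="diatom",
                    compound_class="sterol", units=ug,
                    deepest_station_only=True),
        AnalyteSpec("fatty_acid_C18:2n-6", 20.0, -0.45,
                    organism_group="green_alga", compound_class="fatty_acid",
                    units=ug, deepest_station_only=True),
    ]


@dataclass
class SimulationSpec:
    """Full description of a synthetic study: cores, analytes, community."""

    analytes: list[AnalyteSpec] = field(default_factory=_default_analytes)
    lakes: list[str] = field(default_factory=lambda: ["lake_1"])
    trophic_states: list[str] = field(default_factory=lambda: ["eutrophic"])
    n_stations: int = 3
    depth_max_cm: float = 40.0
    span_years: float = 180.0
    n_layers: int = 20
    min_age: float = 1.0
    #: explicit age grid overriding the depth-derived one (years)
    age_grid: list[float] | None = None
    detection_limit: float | None = None
    community: CommunitySpec | None = field(default_factory=CommunitySpec)

    def __post_init__(self):
        if len(self.trophic_states) != len(self.lakes):
            raise ValueError("one trophic state per lake required")
        if self.n_layers < 3:
            raise ValueError("need >= 3 layers")

    def ages(self) -> np.ndarray:
        if self.age_grid is not None:
            return np.asarray(self.age_grid, dtype=float)
        return np.linspace(self.min_age, self.span_years, self.n_layers)

    def depths(self) -> np.ndarray:
        # constant sedimentation rate: depth proportional to age
        return self.ages() * self.depth_max_cm / self.span_years

    def age_model(self) -> AgeModel:
        return AgeModel([(0.0, 0.0), (self.depth_max_cm, self.span_years)])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_profile(spec: SimulationSpec, analyte: AnalyteSpec,
                     rng: np.random.Generator, lake: str = "lake_1",
                     station: str = "st1") -> AnalyteSeries:
    """One noisy power-law profile: Y_i = a * t_i**b * exp(eps_i).

    Values below the detection limit (if configured) are censored to
    missing; the censored count is recorded on the series.
    """
    ages = spec.ages()
    if ages.size == 0:
        return AnalyteSeries(analyte.analyte_id, np.empty(0), np.empty(0),
                             analyte.organism_group, analyte.compound_class,
                             analyte.units, station, lake)
    eps = rng.normal(0.0, analyte.sigma_log, size=ages.size)
    values = analyte.amplitude * ages ** analyte.exponent * np.exp(eps)
    n_censored = 0
    if spec.detection_limit is not None:
        keep = values >= spec.detection_limit
        n_censored = int((~keep).sum())
        ages, values = ages[keep], values[keep]
    return AnalyteSeries(
        analyte.analyte_id, ages, values, analyte.organism_group,
        analyte.compound_class, analyte.units, station, lake,
        n_censored=n_censored)


def simulate_core(spec: SimulationSpec | None = None,
                  seed: int | None = None) -> list[AnalyteSeries]:
    """All profiles of a synthetic study.

    DNA-type analytes are generated at every station; analytes marked
    ``deepest_station_only`` (biomarkers, macromolecules) only at the last
    station of each lake.  The default preset yields 12 series: 3 DNA
    markers x 3 stations + 3 biomarkers at the deepest station.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(seed)
    out = []
    stations = [f"st{i + 1}" for i in range(spec.n_stations)]
    for lake in spec.lakes:
        for analyte in spec.analytes:
            where = [stations[-1]] if analyte.deepest_station_only else stations
            for st in where:
                out.append(simulate_profile(spec, analyte, rng, lake, st))
    return out


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    raw = proportions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_community(spec: SimulationSpec | None = None,
                       seed: int | None = None):
    """Synthetic amplicon table + qPCR totals, jointly consistent with
    per-group power decay.

    Returns a :class:`~paleodecay.community.CommunityTable`.  Group
    proportions and totals derive from the same intensities, so the
    partition-conservation invariant holds by construction.
    """
    from .community import CommunityTable

    spec = spec or SimulationSpec()
    cspec = spec.community
    if cspec is None:
        raise ValueError("spec has no community block")
    rng = np.random.default_rng(seed)
    ages = spec.ages()
    depths = spec.depths()
    groups = sorted(cspec.group_amplitudes)
    # fixed within-group taxon weights (geometric), identical across samples
    w = 0.5 ** np.arange(cspec.taxa_per_group)
    w = w / w.sum()
    taxa = [f"{g}_taxon{j + 1}" for g in groups
            for j in range(cspec.taxa_per_group)]
    taxon_groups = pd.Series(
        [g for g in groups for _ in range(cspec.taxa_per_group)], index=taxa)

    rows, totals, meta = [], [], []
    for lake, trophic in zip(spec.lakes, spec.trophic_states):
        for t, d in zip(ages, depths):
            intensities = np.array(
                [cspec.group_amplitudes[g] * t ** (-cspec.group_decay[g])
                 for g in groups])
            total = intensities.sum() * np.exp(
                rng.normal(0.0, cspec.total_sigma_log))
            p_group = intensities / intensities.sum()
            p_taxa = np.concatenate([pg * w for pg in p_group])
            if cspec.dirichlet_concentration is not None and np.isfinite(
                    cspec.dirichlet_concentration):
                p_taxa = rng.dirichlet(cspec.dirichlet_concentration * p_taxa)
            if cspec.multinomial_sampling:
                counts = rng.multinomial(cspec.read_depth, p_taxa)
            else:
                counts = _largest_remainder(p_taxa, cspec.read_depth)
            rows.append(counts)
            totals.append(total)
            meta.append({"lake": lake, "station": "deep", "depth_cm": d,
                         "age_y": t, "trophic_state": trophic})

    sample_ids = [f"{m['lake']}_{i % ages.size + 1:02d}"
                  for i, m in enumerate(meta)]
    counts = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    metadata = pd.DataFrame(meta, index=sample_ids)
    return CommunityTable(
        counts=counts,
        taxon_groups=taxon_groups,
        sample_metadata=metadata,
        total_copies=pd.Series(totals, index=sample_ids, name="total_copies"),
    )


# ---------------------------------------------------------------------------
# scenario presets


def scenario_preset(scenario: str, sigma_log: float = DEFAULT_SIGMA_LOG,
                    n_lakes: int = 5) -> SimulationSpec:
    """A study design under which one preservation scenario holds for the
    focal group.

    Five single-station lakes (so each analyte yields 5 decay constants,
    enough for exact rank tests to reach significance), 20 layers over
    180 years.  ``chemical_reactivity``: focal DNA decays much faster than
    the focal resistant compound (diatom-like).  ``biotic_exclusion``:
    focal DNA tracks its resistant compound while other groups' DNA decays
    differently (green-alga-like, algaenan shielding).
    ``adsorption_complexation``: all groups' DNA shares one decay constant.
    """
    copies = "gene copies g-1 dry sediment"
    ug = "ug g-1 dry sediment"
    if scenario == "chemical_reactivity":
        k = {"focal_dna": 1.57, "focal_resistant": 0.52,
             "other1_dna": 0.70, "other2_dna": 0.12}
    elif scenario == "biotic_exclusion":
        k = {"focal_dna": 0.70, "focal_resistant": 0.70,
             "other1_dna": 1.57, "other2_dna": 0.12}
    elif scenario == "adsorption_complexation":
        k = {"focal_dna": 0.70, "focal_resistant": 0.70,
             "other1_dna": 0.70, "other2_dna": 0.70}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    analytes = [
        AnalyteSpec("focal_rbcL", 1e8, -k["focal_dna"], sigma_log,
                    "green_alga", "DNA", copies),
        AnalyteSpec("focal_biomarker", 30.0, -k["focal_resistant"], sigma_log,
                    "green_alga", "fatty_acid", ug),
        AnalyteSpec("other1_rbcL", 1e9, -k["other1_dna"], sigma_log,
                    "diatom", "DNA", copies),
        AnalyteSpec("other2_rbcL", 1e6, -k["other2_dna"], sigma_log,
                    "vascular_plant", "DNA", copies),
    ]
    lakes = [f"lake_{i + 1}" for i in range(n_lakes)]
    trophic = (["eutrophic", "eutrophic", "mesotrophic", "oligotrophic",
                "oligotrophic"] * ((n_lakes + 4) // 5))[:n_lakes]
    return SimulationSpec(analytes=analytes, lakes=lakes,
                          trophic_states=trophic, n_stations=1,
                          community=None)


def write_fixture_bundle(spec: SimulationSpec | None, outdir,
                         seed: int) -> dict:
    """Write a complete seeded input set: profiles.csv, anchors.csv,
    community.csv, totals.csv, samples.csv and manifest.json.

    The CSVs are exactly the long formats the readers in
    :mod:`paleodecay.io` consume, so the bundle runs end-to-end through
    the command-line pipeline.  Identical spec + seed produce
    byte-identical files.
    """
    from . import io as pdio

    spec = spec or SimulationSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = simulate_core(spec, seed=seed)
    model = spec.age_model()
    pdio.write_profiles(series, outdir / "profiles.csv", age_model=model)
    anchors = []
    for lake in spec.lakes:
        for st in [f"st{i + 1}" for i in range(spec.n_stations)]:
            anchors.append({"lake": lake, "station": st, "depth_cm": 0.0,
                            "age_y": 0.0})
            anchors.append({"lake": lake, "station": st,
                            "depth_cm": spec.depth_max_cm,
                            "age_y": spec.span_years})
    pd.DataFrame(anchors).to_csv(outdir / "anchors.csv", index=False)
    manifest = {"seed": seed, "spec": spec.to_dict(),
                "n_series": len(series),
                "n_censored": int(sum(s.n_censored for s in series))}
    if spec.community is not None:
        table = simulate_community(spec, seed=seed + 1)
        pdio.write_community(table, outdir / "community.csv",
                             outdir / "totals.csv", outdir / "samples.csv")
        manifest["n_samples"] = len(table.samples)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
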