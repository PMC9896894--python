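"""Readers/writers for the pipeline's long-format CSV tables.

All tables are UTF-8, comma-separated, one header row, period decimal
mark.  Formats:

* ``profiles.csv``: lake, station, depth_cm, age_y, analyte, value,
  units, organism_group, compound_class — one row per measurement.
* ``anchors.csv``: lake, station, depth_cm, age_y — dated horizons.
* ``community.csv``: sample, taxon, count, group (long format).
* ``totals.csv``: sample, total_copies.
* ``samples.csv``: sample, lake, station, depth_cm, age_y, trophic_state.
* ``fits.csv``: one row per decay fit, full float precision, round-trips.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import AnalyteSeries
from .kinetics import DecayFit

logger = logging.getLogger("paleodecay")

PROFILE_COLUMNS = ["lake", "station", "depth_cm", "age_y", "analyte",
                   "value", "units", "organism_group", "compound_class"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")


def read_profiles(path) -> list[AnalyteSeries]:
    """Read per-sample biomolecule measurements into AnalyteSeries.

    One series per (lake, station, analyte), points sorted by age.  Rows
    with non-numeric or missing values are excluded and logged with their
    line numbers (1-based, header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PROFILE_COLUMNS, path)
    df["_line"] = df.index + 2
    for col in ("age_y", "value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["value"].isna() | df["age_y"].isna()
    if bad.any():
        lines = df.loc[bad, "_line"].tolist()
        logger.warning("%s: %d malformed row(s) excluded at line(s) %s",
                       path, int(bad.sum()), lines)
        df = df[~bad]
    series = []
    for (lake, station, analyte), grp in df.groupby(
            ["lake", "station", "analyte"], sort=True):
        first = grp.iloc[0]
        series.append(AnalyteSeries(
            analyte_id=analyte,
            ages=grp["age_y"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            organism_group=first["organism_group"],
            compound_class=first["compound_class"],
            units=first["units"],
            station_id=station,
            lake_id=lake,
        ))
    return series


def write_profiles(series: list[AnalyteSeries], path,
                   age_model=None) -> None:
    """Write AnalyteSeries to profiles.csv; depth back-computed from the
    age model when one is given, otherwise left empty."""
    rows = []
    for s in series:
        for age, value in zip(s.ages, s.values):
            depth = np.nan
            if age_model is not None:
                # invert the (monotone) model numerically on its anchor grid
                depths = np.array([a.depth for a in age_model.anchors])
                ages = np.array([a.age for a in age_model.anchors])
                depth = float(np.interp(age, ages, depths))
                if age > ages[-1]:
                    rate = (depths[-1] - depths[-2]) / (ages[-1] - ages[-2])
                    depth = float(depths[-1] + (age - ages[-1]) * rate)
            rows.append({"lake": s.lake_id, "station": s.station_id,
                         "depth_cm": depth, "age_y": age,
                         "analyte": s.analyte_id, "value": value,
                         "units": s.units, "organism_group": s.organism_group,
                         "compound_class": s.compound_class})
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_anchors(path) -> dict[tuple[str, str], list[tuple[float, float]]]:
    """Read anchors.csv into {(lake, station): [(depth, age), ...]}."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["lake", "station", "depth_cm", "age_y"], path)
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (lake, station), grp in df.groupby(["lake", "station"], sort=True):
        out[(lake, station)] = list(
            zip(grp["depth_cm"].astype(float), grp["age_y"].astype(float)))
    return out


_FIT_FIELDS = [f.name for f in dataclasses.fields(DecayFit)]


def write_fits(fits: list[DecayFit], path) -> None:
    """One row per fit; floats stored at full repr precision so that
    read_fits(write_fits(x)) reproduces x exactly."""
    rows = [dataclasses.asdict(f) for f in fits]
    # repr round-trips floats exactly; pandas' default CSV formatting does not
    pd.DataFrame(rows, columns=_FIT_FIELDS).to_csv(path, index=False,
                                                   float_format=lambda v: repr(float(v)))


def read_fits(path) -> list[DecayFit]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    _require_columns(df, _FIT_FIELDS, path)
    fits = []
    for _, row in df.iterrows():
        kw = row.to_dict()
        kw["decay_constant"] = (None if pd.isna(kw["decay_constant"])
                                else float(kw["decay_constant"]))
        kw["flagged"] = bool(kw["flagged"])
        kw["n_points"] = int(kw["n_points"])
        kw["n_excluded"] = int(kw["n_excluded"])
        for key in ("analyte_id", "organism_group", "compound_class",
                    "station_id", "lake_id"):
            kw[key] = "" if pd.isna(kw[key]) else str(kw[key])
        fits.append(DecayFit(**kw))
    return fits


def read_community(community_path, totals_path=None, samples_path=None):
    """Assemble a CommunityTable from the long-format community.csv plus
    optional totals.csv and samples.csv."""
    from .community import CommunityTable

    df = pd.read_csv(Path(community_path))
    _require_columns(df, ["sample", "taxon", "count", "group"], community_path)
    counts = df.pivot_table(index="sample", columns="taxon", values="count",
                            fill_value=0, aggfunc="sum", sort=True)
    counts = counts.astype(int)
    taxon_groups = df.drop_duplicates("taxon").set_index("taxon")["group"]
    dup = df.groupby("taxon")["group"].nunique()
    if (dup > 1).any():
        raise ValueError(f"taxa with multiple group assignments: "
                         f"{list(dup.index[dup > 1])}")
    totals = None
    if totals_path is not None:
        tdf = pd.read_csv(Path(totals_path))
        _require_columns(tdf, ["sample", "total_copies"], totals_path)
        totals = tdf.set_index("sample")["total_copies"].astype(float)
        totals = totals.reindex(counts.index).dropna()
    metadata = pd.DataFrame(index=counts.index)
    if samples_path is not None:
        metadata = pd.read_csv(Path(samples_path)).set_index("sample")
        metadata = metadata.reindex(counts.index)
    return CommunityTable(counts=counts, taxon_groups=taxon_groups,
                          sample_metadata=metadata, total_copies=totals)


def write_community(table, community_path, totals_path=None,
                    samples_path=None) -> None:
    rows = []
    for sample in table.counts.index:
        for taxon in table.counts.columns:
            rows.append({"sample": sample, "taxon": taxon,
                         "count": int(table.counts.at[sample, taxon]),
                         "group": table.taxon_groups[taxon]})
    pd.DataFrame(rows).to_csv(community_path, index=False)
    if totals_path is not None and table.total_copies is not None:
        table.total_copies.rename("total_copies").to_csv(totals_path,
                                                         index_label="sample")
    if samples_path is not None and len(table.sample_metadata.columns):
        table.sample_metadata.to_csv(samples_path, index_label="sample")


@dataclass
class RunConfig:
    """Run configuration: paths, fit options and stochastic settings.

    A seed is mandatory whenever any stochastic operation (permutation
    tests, simulation) is enabled.  The config hash ties log lines and
    outputs back to the exact settings used.
    """

    profiles: str = "profiles.csv"
    anchors: str | None = None
    output_dir: str = "out"
    log_base: str = "e"
    min_points: int = 3
    zero_policy: str = "exclude"
    half_life_formula: str = "exact_halving"
    n_permutations: int = 999
    seed: int | None = None
    adjustment: str = "none"
    stochastic: bool = False

    def __post_init__(self):
        if self.stochastic and self.seed is None:
            raise ValueError("seed is mandatory when stochastic operations "
                             "are enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def setup_logging(self, level=logging.INFO) -> None:
        logging.basicConfig(
            level=level,
            format=(f"%(asctime)s [cfg {self.config_hash} seed {self.seed}] "
                    "%(levelname)s %(name)s: %(message)s"))
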