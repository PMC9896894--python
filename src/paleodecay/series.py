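"""The per-analyte depth/age profile container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORGANISM_GROUPS = (
    "diatom",
    "green_alga",
    "microalgae_general",
    "vascular_plant",
    "other",
)

COMPOUND_CLASSES = (
    "DNA",
    "fatty_acid",
    "n_alkane",
    "sterol",
    "pigment",
    "lignin",
    "macromolecule",
    "other",
)


@dataclass
class AnalyteSeries:
    """One biomolecule's (age, value) record in a single core.

    ``values`` are contents per g dry sediment (gene copies, µg, or % of
    pyrolysis products depending on ``units``); ``ages`` are years since
    deposition.  Points are kept sorted by increasing age, values must be
    nonnegative; ages used for power-law fitting must additionally be
    strictly positive (enforced at fit time, not here, so that surface
    layers can be carried through I/O).
    """

    analyte_id: str
    ages: np.ndarray
    values: np.ndarray
    organism_group: str = "other"
    compound_class: str = "other"
    units: str = ""
    station_id: str = ""
    lake_id: str = ""
    n_censored: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if self.organism_group not in ORGANISM_GROUPS:
            raise ValueError(
                f"unknown organism_group {self.organism_group!r}; "
                f"expected one of {ORGANISM_GROUPS}"
            )
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"unknown compound_class {self.compound_class!r}; "
                f"expected one of {COMPOUND_CLASSES}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"negative values in series {self.analyte_id!r}")
        order = np.argsort(self.ages, kind="stable")
        self.ages = self.ages[order]
        self.values = self.values[order]

    def __len__(self) -> int:
        return self.ages.size

    @property
    def label(self) -> str:
        return f"{self.lake_id}/{self.station_id}/{self.analyte_id}".strip("/")

    def positive_subset(self) -> tuple[np.ndarray, np.ndarray, int]:
        """Points usable for log-space fitting: age > 0 and value > 0.

        Returns (ages, values, n_dropped).  Zeros (non-detects) and surface
        ages are excluded rather than imputed; see the zero-handling policy
        in the fitting module.
        """
        mask = (self.ages > 0) & (self.values > 0)
        return self.ages[mask], self.values[mask], int((~mask).sum())
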