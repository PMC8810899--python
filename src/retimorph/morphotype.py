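"""Morphotype-defining criterion.

Five microglial morphotypes are distinguished on cell-body
morphometry alone: ramified, hyper-ramified, activated, rod and
amoeboid.  The criterion is a deterministic cascade over the measured
record:

1. ramified        iff F_max < 13.201 um (the reference minimum F_max
                   of an amoeboid body; ramified bodies are smaller);
2. rod             iff FDR >= 3 (elongation cut-off separating rod
                   from hyper-ramified bodies; ties count as rod);
3. amoeboid        iff solidity >= 0.90 (smooth compact body);
4. hyper-ramified  iff area >= 60 um^2 and circularity < 0.6
                   (large lobular body with a rough outline);
5. activated       otherwise.

The F_max and FDR cut-offs are quantitative; steps 3-5 are a
deterministic surrogate for descriptors that are partly qualitative
in practice (see docs/methods.md), with every bound configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .particle_analysis import CellRecord


class MorphotypeLabel(str, Enum):
    RAMIFIED = "ramified"
    HYPER_RAMIFIED = "hyper_ramified"
    ACTIVATED = "activated"
    ROD = "rod"
    AMOEBOID = "amoeboid"


#: canonical class order used for tables, confusion matrices and ROC
LABEL_ORDER = [
    MorphotypeLabel.RAMIFIED,
    MorphotypeLabel.HYPER_RAMIFIED,
    MorphotypeLabel.ACTIVATED,
    MorphotypeLabel.ROD,
    MorphotypeLabel.AMOEBOID,
]


@dataclass
class MorphotypeCriterion:
    """Cut-offs of the deterministic classification cascade.

    ``fmax_ramified_cutoff`` and ``hyper_area_min`` are in micrometres
    (um and um^2); the remaining bounds are dimensionless ratios.
    """

    fmax_ramified_cutoff: float = 13.201  # um
    fdr_rod_cutoff: float = 3.0
    amoeboid_solidity_min: float = 0.90
    hyper_area_min: float = 60.0  # um^2
    hyper_circularity_max: float = 0.6

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fdr_rod_cutoff <= 1:
            raise ValueError("fdr_rod_cutoff must be > 1")


def apply_criterion(
    record: CellRecord | dict | pd.Series,
    criterion: MorphotypeCriterion | None = None,
    scale_um_per_px: float = 0.636,
) -> MorphotypeLabel:
    """Assign a morphotype label to one measured cell record.

    ``record`` may be a CellRecord or any mapping exposing
    ``feret_max`` (px), ``fdr``, ``solidity``, ``area`` (px^2) and
    ``circularity``; pixel quantities are converted to micrometres
    with ``scale_um_per_px``.
    """
    c = criterion or MorphotypeCriterion()
    if isinstance(record, CellRecord):
        get = record.values.__getitem__
    else:
        def get(k):
            try:
                return record[k]
            except (KeyError, IndexError) as exc:
                raise ValueError(f"record missing parameter {k!r}") from exc
    try:
        fmax_um = float(get("feret_max")) * scale_um_per_px
        fdr = float(get("fdr"))
        solidity = float(get("solidity"))
        area_um2 = float(get("area")) * scale_um_per_px**2
        circularity = float(get("circularity"))
    except (KeyError, TypeError) as exc:
        raise ValueError("record missing required parameters") from exc
    for name, v in [("fdr", fdr), ("solidity", solidity)]:
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name}")

    if fmax_um < c.fmax_ramified_cutoff:
        return MorphotypeLabel.RAMIFIED
    if fdr >= c.fdr_rod_cutoff:
        return MorphotypeLabel.ROD
    if solidity >= c.amoeboid_solidity_min:
        return MorphotypeLabel.AMOEBOID
    if area_um2 >= c.hyper_area_min and circularity < c.hyper_circularity_max:
        return MorphotypeLabel.HYPER_RAMIFIED
    return MorphotypeLabel.ACTIVATED


def label_frame(
    table: pd.DataFrame,
    criterion: MorphotypeCriterion | None = None,
    scale_um_per_px: float = 0.636,
) -> pd.Series:
    """Vectorised criterion over a feature table; returns label strings."""
    return table.apply(
        lambda row: apply_criterion(row, criterion, scale_um_per_px).value, axis=1
    )


def compile_training(
    pool: pd.DataFrame,
    per_class_n: int = 240,
    seed: int = 0,
    label_column: str = "morphotype",
) -> pd.DataFrame:
    """Compile a balanced training table from a labelled record pool.

    Samples ``per_class_n`` rows per morphotype without replacement
    with the given seed.  Raises if any class is under-populated,
    naming the deficient class.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for label in LABEL_ORDER:
        sub = pool[pool[label_column] == label.value]
        if len(sub) < per_class_n:
            raise ValueError(
                f"class {label.value!r} has only {len(sub)} records, "
                f"need {per_class_n}"
            )
        idx = rng.choice(len(sub), size=per_class_n, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def save_training(
    table: pd.DataFrame,
    path: str | Path,
    criterion: MorphotypeCriterion | None = None,
    seed: int | None = None,
) -> None:
    """Write the training table CSV plus a JSON sidecar of provenance."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {
        "criterion": asdict(criterion or MorphotypeCriterion()),
        "seed": seed,
        "n_rows": int(len(table)),
        "columns": [c for c in table.columns],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
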