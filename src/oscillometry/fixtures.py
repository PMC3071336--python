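"""Built-in reference tables: published group-averaged IOS values.

Small, exact copies of group-mean tables from the two-year paediatric
bronchodilator study this package's cohort design emulates: averaged SAI
impedance spectra at baseline (with and without one overweight child — the
study's robustness check), and the group-mean trajectories of the IOS
indices and fitted circuit constants. They serve as cross-check inputs:
recomputing indices or percent changes from these cells must reproduce the
published derived numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import ImpedanceSpectrum

__all__ = ["Fixture", "load_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class Fixture:
    name: str
    payload: object  # ImpedanceSpectrum or DataFrame
    note: str


_IOS_GRID = (3.0, 5.0, 10.0, 15.0, 20.0, 25.0, 35.0)

# Averaged SAI spectra, 2006 baseline. OC = overweight child included,
# NOC = excluded. Values exactly as published.
_TABLE7 = {
    "table7_oc": (
        (0.86, 0.72, 0.55, 0.43, 0.41, 0.47, 0.59),
        (-0.40, -0.32, -0.21, -0.12, 0.02, 0.11, 0.20),
    ),
    "table7_noc": (
        (0.86, 0.71, 0.54, 0.42, 0.40, 0.46, 0.59),
        (-0.41, -0.33, -0.21, -0.12, 0.02, 0.12, 0.21),
    ),
}

_STAGES = ((2006, "preB"), (2008, "preB"), (2008, "postB"))


def _stage_frame(per_group: dict[str, dict[str, tuple[float, float, float]]]) -> pd.DataFrame:
    rows = []
    for group, cols in per_group.items():
        for i, (visit, cond) in enumerate(_STAGES):
            rows.append(
                {"group": group, "visit": visit, "condition": cond}
                | {name: vals[i] for name, vals in cols.items()}
            )
    return pd.DataFrame(rows)


def _table2() -> pd.DataFrame:
    # Group-mean IOS indices (kPa·s/L; AX kPa/L) per stage.
    return _stage_frame(
        {
            "SAI": {"R5": (0.73, 0.63, 0.53), "fdR": (0.31, 0.27, 0.20), "AX": (2.51, 2.00, 1.34)},
            "H": {"R5": (0.52, 0.43, 0.38), "fdR": (0.15, 0.13, 0.08), "AX": (1.09, 0.80, 0.57)},
        }
    )


def _table3() -> pd.DataFrame:
    # Group-mean fitted Rp (kPa·s/L) and Cp (L/kPa) per stage and model.
    frames = []
    for model, per_group in (
        ("aric", {"SAI": {"Rp": (0.592, 0.470, 0.359), "Cp": (0.053, 0.056, 0.067)},
                  "H": {"Rp": (0.451, 0.438, 0.316), "Cp": (0.100, 0.136, 0.162)}}),
        ("eric", {"SAI": {"Rp": (0.824, 0.601, 0.472), "Cp": (0.045, 0.056, 0.076)},
                  "H": {"Rp": (0.501, 0.472, 0.386), "Cp": (0.115, 0.155, 0.173)}}),
    ):
        f = _stage_frame(per_group)
        f.insert(1, "model", model)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _table6() -> pd.DataFrame:
    # Published growth / bronchodilator percent changes (integer percent).
    rows = []
    data = {
        "R5": (-17, -12, -14, -16),
        "fdR": (-13, -38, -13, -26),
        "AX": (-27, -29, -20, -33),
        "aric Rp": (-3, -28, -21, -24),
        "aric Cp": (35, 19, 4, 20),
        "eric Rp": (-6, -18, -27, -21),
        "eric Cp": (35, 12, 25, 35),
    }
    for param, (hg, hb, sg, sb) in data.items():
        for group, contrast, pct in (
            ("H", "growth", hg), ("H", "bronchodilator", hb),
            ("SAI", "growth", sg), ("SAI", "bronchodilator", sb),
        ):
            rows.append({"group": group, "contrast": contrast, "parameter": param, "percent": pct})
    return pd.DataFrame(rows)


def _table8() -> pd.DataFrame:
    # Time-change summary: R5, AX and the eRIC Cp trajectories.
    return _stage_frame(
        {
            "SAI": {"R5": (0.73, 0.63, 0.53), "AX": (2.51, 2.00, 1.34), "Cp": (0.045, 0.056, 0.076)},
            "H": {"R5": (0.52, 0.43, 0.38), "AX": (1.09, 0.80, 0.57), "Cp": (0.115, 0.155, 0.173)},
        }
    )


def _builders() -> dict[str, tuple]:
    return {
        "table7_oc": (
            lambda: ImpedanceSpectrum(_IOS_GRID, *_TABLE7["table7_oc"]),
            "Averaged SAI impedance spectrum, 2006 baseline, overweight child included.",
        ),
        "table7_noc": (
            lambda: ImpedanceSpectrum(_IOS_GRID, *_TABLE7["table7_noc"]),
            "Averaged SAI impedance spectrum, 2006 baseline, overweight child excluded.",
        ),
        "table2_means": (_table2, "Group-mean IOS indices per visit-condition stage."),
        "table3_means": (_table3, "Group-mean fitted Rp/Cp per stage for both circuit models."),
        "table6_percent": (_table6, "Published growth and bronchodilator percent changes."),
        "table8_means": (_table8, "Group-mean R5, AX and eRIC Cp trajectories."),
    }


FIXTURE_NAMES = tuple(_builders())


def load_fixture(name: str) -> Fixture:
    """Load a built-in reference table by name.

    Unknown names raise ``KeyError`` listing the available fixtures.
    """
    builders = _builders()
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(builders)}")
    build, note = builders[name]
    return Fixture(name=name, payload=build(), note=note)
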