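"""Screening-analysis statistics for plate-based enzyme panels.

Detection of reaction product follows a two-tier rule: a product quantified
by UV at the isosbestic-point channel is "quantified"; otherwise it is
"detectable" when its mass-spectrometry ion-count peak area strictly exceeds
a threshold derived from negative-control wells (by default the control
mean plus three sample standard deviations); otherwise "not detected".
Substrate promiscuity per enzyme is the percentage of the substrate panel
with at least detectable product.

Control statistics are computed per substrate (each substrate has its own
background) unless pooled explicitly by the caller.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


class Call(str, enum.Enum):
    QUANTIFIED = "quantified"      # UV-quantified yield available
    DETECTABLE = "detectable"      # MS signal above background, below UV limit
    NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class PlateMeasurement:
    """One enzyme x substrate measurement (replicate-averaged)."""

    enzyme: str
    substrate: str
    ms_area: float
    uv_yield: float | None = None  # percent, when UV-quantifiable

    def __post_init__(self) -> None:
        if self.ms_area < 0:
            raise ValueError("ms_area must be non-negative")
        if self.uv_yield is not None and not 0 <= self.uv_yield <= 100:
            raise ValueError("uv_yield must be a percent in [0, 100]")


@dataclass(frozen=True)
class DetectionCall:
    enzyme: str
    substrate: str
    call: Call
    threshold: float


def ms_detection_threshold(
    control_areas: Sequence[float], rule: str = "mean_plus_3sd"
) -> float:
    """Detection threshold from negative-control peak areas.

    ``mean_plus_3sd`` (default): mean(control) + 3·sd(control) with the
    sample (n-1) standard deviation. ``3sd`` is the literal alternative
    reading, 3·sd(control) alone. At least 2 replicates are required.
    """
    if len(control_areas) < 2:
        raise ValueError("need at least 2 control replicates for a threshold")
    sd = statistics.stdev(control_areas)
    if rule == "mean_plus_3sd":
        return statistics.mean(control_areas) + 3.0 * sd
    if rule == "3sd":
        return 3.0 * sd
    raise ValueError(f"unknown threshold rule {rule!r}")


def call_detection(meas: PlateMeasurement, threshold: float) -> DetectionCall:
    """Classify one measurement against a control-derived threshold.

    A present UV yield wins outright; otherwise the MS area must strictly
    exceed the threshold to count as detectable.
    """
    if meas.uv_yield is not None:
        call = Call.QUANTIFIED
    elif meas.ms_area > threshold:
        call = Call.DETECTABLE
    else:
        call = Call.NOT_DETECTED
    return DetectionCall(
        enzyme=meas.enzyme, substrate=meas.substrate, call=call, threshold=threshold
    )


def promiscuity_fraction(calls: Iterable[DetectionCall], n_substrates: int) -> float:
    """Percent of the substrate panel accepted (quantified or detectable)."""
    seen: set[str] = set()
    accepted = 0
    for c in calls:
        if c.substrate in seen:
            raise ValueError(f"duplicate call for substrate {c.substrate!r}")
        seen.add(c.substrate)
        if c.call in (Call.QUANTIFIED, Call.DETECTABLE):
            accepted += 1
    if len(seen) > n_substrates:
        raise ValueError("more calls than substrates in the panel")
    return 100.0 * accepted / n_substrates


def analyze_plate(
    plate: pd.DataFrame, rule: str = "mean_plus_3sd"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a tidy plate table and summarize per-enzyme promiscuity.

    ``plate`` columns: enzyme, substrate, replicate, uv_yield (blank when
    below the UV limit), ms_area, is_control (boolean; negative-control
    wells). Replicates are averaged per enzyme x substrate (a UV yield is
    "present" if any replicate has one); thresholds are computed per
    substrate from the control wells.

    Returns (calls table, per-enzyme summary with percent_accepted).
    """
    required = {"enzyme", "substrate", "replicate", "uv_yield", "ms_area", "is_control"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    thresholds = {
        substrate: ms_detection_threshold(grp["ms_area"].tolist(), rule)
        for substrate, grp in plate[plate["is_control"]].groupby("substrate")
    }

    rows = []
    samples = plate[~plate["is_control"]]
    for (enzyme, substrate), grp in samples.groupby(["enzyme", "substrate"]):
        if substrate not in thresholds:
            raise ValueError(f"no control wells for substrate {substrate!r}")
        uv = grp["uv_yield"].dropna()
        meas = PlateMeasurement(
            enzyme=enzyme,
            substrate=substrate,
            ms_area=float(grp["ms_area"].mean()),
            uv_yield=float(uv.mean()) if len(uv) else None,
        )
        dc = call_detection(meas, thresholds[substrate])
        rows.append(
            {
                "enzyme": enzyme,
                "substrate": substrate,
                "ms_area": meas.ms_area,
                "uv_yield": meas.uv_yield,
                "threshold": dc.threshold,
                "call": dc.call.value,
            }
        )
    calls = pd.DataFrame(rows).sort_values(["enzyme", "substrate"]).reset_index(drop=True)

    n_substrates = calls["substrate"].nunique()
    summary = (
        calls.assign(accepted=calls["call"] != Call.NOT_DETECTED.value)
        .groupby("enzyme", as_index=False)
        .agg(n_accepted=("accepted", "sum"))
    )
    summary["n_substrates"] = n_substrates
    summary["percent_accepted"] = 100.0 * summary["n_accepted"] / n_substrates
    return calls, summary
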