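"""Small-animal FDG-PET quantification from ROI-level activity concentrations.

The chain is: final injected dose (initial minus residual), percent injected
dose per gram of tissue (%ID/g, using the 1 ml = 1 g tissue convention),
reference-region normalization to the cerebellum (which lacks D2-type
receptors, so its uptake is condition-independent), and the per-animal ratio
of uptake under magnetic-field stimulation over baseline.  Left and right
dorsal striata are averaged before any ratio is formed.  No radioactive-decay
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PetMeasurement",
    "final_dose",
    "percent_id_per_g",
    "reference_ratio",
    "dmf_over_baseline",
    "quantify_table",
    "MBQ_PER_MCI",
    "mbq_to_uci",
    "uci_to_mbq",
]

MBQ_PER_MCI = 37.0  # 1 mCi = 37 MBq exactly


def mbq_to_uci(x):
    """Convert MBq to microcuries."""
    return np.asarray(x, dtype=float) * 1000.0 / MBQ_PER_MCI


def uci_to_mbq(x):
    """Convert microcuries to MBq."""
    return np.asarray(x, dtype=float) * MBQ_PER_MCI / 1000.0


@dataclass(frozen=True)
class PetMeasurement:
    """One animal x condition measurement.

    Concentrations in MBq/ml, doses in MBq, weight in g.
    """

    animal: str
    condition: str  # 'baseline' or 'DMF'
    c_striatum_L: float
    c_striatum_R: float
    c_cerebellum: float
    dose_initial: float
    dose_residual: float
    weight: float

    def __post_init__(self) -> None:
        if not self.dose_initial > self.dose_residual >= 0:
            raise ValueError("require dose_initial > dose_residual >= 0")
        if min(self.c_striatum_L, self.c_striatum_R, self.c_cerebellum) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def c_striatum(self) -> float:
        """Left/right dorsal striata averaged."""
        return 0.5 * (self.c_striatum_L + self.c_striatum_R)


def final_dose(m: PetMeasurement) -> float:
    """Injected dose actually delivered: initial minus residual (MBq)."""
    dose = m.dose_initial - m.dose_residual
    if dose <= 0:
        raise ValueError("final dose must be positive")
    return float(dose)


def percent_id_per_g(m: PetMeasurement) -> dict[str, float]:
    """%ID/g per region: 100 * C / (final dose / weight), 1 ml = 1 g tissue."""
    dose_per_g = final_dose(m) / m.weight
    if dose_per_g <= 0:
        raise ValueError("dose per gram must be positive")
    return {
        "striatum": 100.0 * m.c_striatum / dose_per_g,
        "striatum_L": 100.0 * m.c_striatum_L / dose_per_g,
        "striatum_R": 100.0 * m.c_striatum_R / dose_per_g,
        "cerebellum": 100.0 * m.c_cerebellum / dose_per_g,
    }


def reference_ratio(m: PetMeasurement) -> float:
    """Averaged striatal uptake over cerebellar uptake.

    The injected dose and weight cancel, so the ratio is identical whether
    formed from raw concentrations or %ID/g, and it is invariant to any
    global scanner calibration factor.
    """
    if m.c_cerebellum <= 0:
        raise ValueError("cerebellum concentration must be positive")
    return float(m.c_striatum / m.c_cerebellum)


def dmf_over_baseline(
    m_baseline: PetMeasurement, m_dmf: PetMeasurement
) -> dict[str, float]:
    """Per-animal DMF-over-baseline uptake ratios.

    Returned for both the raw striatal concentration (MBq/ml) and the
    cerebellum-referenced measure.
    """
    if m_baseline.animal != m_dmf.animal:
        raise ValueError(
            f"unmatched animals: {m_baseline.animal!r} vs {m_dmf.animal!r}"
        )
    if m_baseline.c_striatum <= 0:
        raise ValueError("baseline striatal concentration must be positive")
    raw = m_dmf.c_striatum / m_baseline.c_striatum
    ref = reference_ratio(m_dmf) / reference_ratio(m_baseline)
    return {"ratio_raw": float(raw), "ratio_cerebellum_norm": float(ref)}


def _row_measurement(row: pd.Series) -> PetMeasurement:
    return PetMeasurement(
        animal=str(row["animal"]),
        condition=str(row["condition"]),
        c_striatum_L=float(row["c_striatum_L"]),
        c_striatum_R=float(row["c_striatum_R"]),
        c_cerebellum=float(row["c_cerebellum"]),
        dose_initial=float(row["dose_initial_MBq"]),
        dose_residual=float(row["dose_residual_MBq"]),
        weight=float(row["weight_g"]),
    )


def quantify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Full quantification of a long-form cohort table.

    Input columns: ``animal, condition, c_striatum_L, c_striatum_R,
    c_cerebellum, dose_initial_MBq, dose_residual_MBq, weight_g`` with
    conditions 'baseline' and 'DMF' per animal.  Output: one row per animal
    with per-condition %ID/g and reference ratios plus the DMF-over-baseline
    ratios (raw and cerebellum-normalized).
    """
    rows = []
    for animal, sub in table.groupby("animal", sort=True):
        by_cond = {str(r["condition"]): _row_measurement(r) for _, r in sub.iterrows()}
        if set(by_cond) != {"baseline", "DMF"}:
            raise ValueError(
                f"animal {animal!r} must have exactly one baseline and one DMF row"
            )
        mb, md = by_cond["baseline"], by_cond["DMF"]
        idg_b, idg_d = percent_id_per_g(mb), percent_id_per_g(md)
        ratios = dmf_over_baseline(mb, md)
        rows.append(
            {
                "animal": animal,
                "pct_idg_striatum_baseline": idg_b["striatum"],
                "pct_idg_striatum_dmf": idg_d["striatum"],
                "pct_idg_cerebellum_baseline": idg_b["cerebellum"],
                "pct_idg_cerebellum_dmf": idg_d["cerebellum"],
                "ref_ratio_baseline": reference_ratio(mb),
                "ref_ratio_dmf": reference_ratio(md),
                **ratios,
            }
        )
    return pd.DataFrame(rows)
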