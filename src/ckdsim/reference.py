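"""Published national-scale results used as worked-example inputs.

The source study reports its accumulated 10-year outcome table (eligible
patients, cardiovascular and kidney-failure event counts, costs in million
EUR, QALY gains and NMB) for SGLT2i uptakes of 15 %, 50 % and 90 % at the
report years 2026 / 2031 / 2036.  Those printed aggregates are inputs
here: the functions below reproduce the study's *derived* arithmetic -
eligibility counts, growth percentages, event deltas, category savings and
the net monetary benefit identity - from the printed values, independently
of the microsimulation.
"""

from __future__ import annotations

import pandas as pd

from .economics import DEFAULT_LAMBDA, compute_savings, net_monetary_benefit
from .population import compute_eligible, growth_percentage

UPTAKES = (0.15, 0.50, 0.90)
REPORT_YEARS = (2026, 2031, 2036)

#: accumulated outcomes by (report year, uptake); costs in million EUR
PUBLISHED_TABLE = {
    (2026, 0.15): dict(eligible=67_395, mace=801, new_hf=337, cvd_hosp=2_259,
                       kf_krt=382, hd=375, pd=0, tx=7, cost_krt=25.6,
                       cost_cvd=178.3, cost_total=542.7, qaly_gain=0, nmb=0.0),
    (2026, 0.50): dict(eligible=67_395, mace=801, new_hf=337, cvd_hosp=2_235,
                       kf_krt=382, hd=375, pd=0, tx=7, cost_krt=25.6,
                       cost_cvd=177.1, cost_total=554.8, qaly_gain=71, nmb=-11.9),
    (2026, 0.90): dict(eligible=67_395, mace=801, new_hf=337, cvd_hosp=2_208,
                       kf_krt=382, hd=375, pd=0, tx=7, cost_krt=25.6,
                       cost_cvd=175.8, cost_total=568.6, qaly_gain=150, nmb=-25.5),
    (2031, 0.15): dict(eligible=81_458, mace=1_979, new_hf=2_220, cvd_hosp=12_011,
                       kf_krt=973, hd=832, pd=215, tx=373, cost_krt=117.2,
                       cost_cvd=1_134.2, cost_total=3_269.5, qaly_gain=0, nmb=0.0),
    (2031, 0.50): dict(eligible=81_560, mace=1_982, new_hf=2_202, cvd_hosp=11_796,
                       kf_krt=888, hd=747, pd=215, tx=376, cost_krt=109.3,
                       cost_cvd=1_120.6, cost_total=3_255.1, qaly_gain=534, nmb=-2.8),
    (2031, 0.90): dict(eligible=81_677, mace=1_985, new_hf=2_182, cvd_hosp=11_550,
                       kf_krt=791, hd=649, pd=215, tx=379, cost_krt=100.3,
                       cost_cvd=1_105.1, cost_total=3_273.1, qaly_gain=1_145, nmb=-5.9),
    (2036, 0.15): dict(eligible=87_256, mace=3_380, new_hf=3_180, cvd_hosp=17_689,
                       kf_krt=2_334, hd=1_865, pd=702, tx=752, cost_krt=493.7,
                       cost_cvd=2_696.1, cost_total=7_815.2, qaly_gain=0, nmb=0.0),
    (2036, 0.50): dict(eligible=87_588, mace=3_406, new_hf=3_133, cvd_hosp=17_366,
                       kf_krt=1_884, hd=1_472, pd=580, tx=660, cost_krt=385.0,
                       cost_cvd=2_661.2, cost_total=7_681.1, qaly_gain=2_920, nmb=204.0),
    (2036, 0.90): dict(eligible=87_967, mace=3_435, new_hf=3_078, cvd_hosp=16_991,
                       kf_krt=1_364, hd=1_017, pd=438, tx=554, cost_krt=261.1,
                       cost_cvd=2_621.4, cost_total=7_528.3, qaly_gain=6_279, nmb=438.0),
}

#: reported national population anchors
INITIAL_TOTAL_CKD = 251_946
FINAL_TOTAL_CKD = 328_414
ANNUAL_INCIDENCE = 27_816
ELIGIBILITY_FRACTION = 0.2675
#: reported 10-year outcome rates (fractions) by uptake
REPORTED_KF_RISK = {0.15: 0.085, 0.50: 0.066, 0.90: 0.045}
REPORTED_MORTALITY = {0.15: 0.543, 0.50: 0.539, 0.90: 0.535}


def published_frame() -> pd.DataFrame:
    """The published accumulated outcome table as a tidy DataFrame."""
    rows = []
    for (year, uptake), vals in PUBLISHED_TABLE.items():
        rows.append({"report_year": year, "uptake": uptake, **vals})
    return pd.DataFrame(rows).sort_values(["report_year", "uptake"]).reset_index(drop=True)


def worked_example(lam: float = DEFAULT_LAMBDA) -> dict[str, float]:
    """Recompute the study's derived quantities from its printed inputs.

    Eligibility counts come from the floor rule on the population anchors;
    growth percentages, event deltas and category savings are differences
    of printed cells; NMB follows the lambda identity applied to the printed
    QALY gains and total costs.  All values are on the scale the source
    prints (counts, percentages, million EUR).
    """
    t15, t50, t90 = (PUBLISHED_TABLE[(2036, u)] for u in UPTAKES)

    out: dict[str, float] = {}
    out["eligible_2026"] = compute_eligible(INITIAL_TOTAL_CKD, ELIGIBILITY_FRACTION)
    out["eligible_incident_annual"] = compute_eligible(ANNUAL_INCIDENCE, ELIGIBILITY_FRACTION)
    out["eligible_prevalent"] = out["eligible_2026"] - out["eligible_incident_annual"]
    out["total_ckd_growth_pct"] = growth_percentage(INITIAL_TOTAL_CKD, FINAL_TOTAL_CKD)
    # the eligible growth uses the 15 %-uptake eligible trajectory endpoints
    out["eligible_growth_pct"] = growth_percentage(
        PUBLISHED_TABLE[(2026, 0.15)]["eligible"], PUBLISHED_TABLE[(2036, 0.15)]["eligible"]
    )

    for uptake, t in ((0.50, t50), (0.90, t90)):
        tag = f"{int(uptake * 100)}"
        out[f"mace_delta_{tag}"] = t["mace"] - t15["mace"]
        out[f"new_hf_delta_{tag}"] = t["new_hf"] - t15["new_hf"]
        out[f"cvd_hosp_delta_{tag}"] = t["cvd_hosp"] - t15["cvd_hosp"]
        out[f"kf_krt_delta_{tag}"] = t["kf_krt"] - t15["kf_krt"]
        out[f"krt_initiations_delta_{tag}"] = (
            (t["hd"] + t["pd"] + t["tx"]) - (t15["hd"] + t15["pd"] + t15["tx"])
        )
        savings = compute_savings(
            {"krt": t15["cost_krt"], "cvd": t15["cost_cvd"], "total": t15["cost_total"]},
            {"krt": t["cost_krt"], "cvd": t["cost_cvd"], "total": t["cost_total"]},
        )
        out[f"krt_savings_meur_{tag}"] = round(savings["krt"], 1)
        out[f"cvd_savings_meur_{tag}"] = round(savings["cvd"], 1)
        out[f"total_savings_meur_{tag}"] = round(savings["total"], 1)
        delta_cost_meur = t["cost_total"] - t15["cost_total"]
        nmb_meur = net_monetary_benefit(t["qaly_gain"], delta_cost_meur * 1e6, lam) / 1e6
        out[f"nmb_meur_{tag}"] = round(nmb_meur, 1)
    return out
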