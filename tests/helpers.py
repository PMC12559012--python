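"""Hand-rolled builders and an independent brute-force weighting oracle."""

from collections import Counter

import pandas as pd

import denomweight as dw


def make_cohort(rows):
    """Build a prepared-cohort frame from dicts with age/sex/region/engaged."""
    recs = []
    for i, r in enumerate(rows, start=1):
        age = r["age"]
        recs.append(
            {
                "record_row_id": i,
                "pseudo_id": f"P{i:06d}",
                "age_years": age,
                "sex": r.get("sex", "F"),
                "region": r.get("region", dw.REGIONS[0]),
                "vaccinated": int(r.get("vaccinated", 1)),
                "engaged": bool(r.get("engaged", True)),
                "age_band": dw.assign_age_band(age),
                "stratum_age": "90+" if age >= 90 else str(age),
            }
        )
    return pd.DataFrame(recs)


def make_reference(entries):
    """Reference table from (age_year, sex, region, count) tuples."""
    return pd.DataFrame(entries, columns=["age_year", "sex", "region", "count"])


def brute_force_weights(cohort_rows, reference_counts):
    """Recompute the whole weighting from scratch with plain Python.

    ``cohort_rows``: list of dicts with stratum_age/sex/region/engaged.
    ``reference_counts``: dict mapping (age, sex, region) -> N.
    Returns (initial, final, summary_dict); no pandas, no shared code
    with the implementation.
    """
    strata = [(r["stratum_age"], r["sex"], r["region"]) for r in cohort_rows]
    n = Counter(strata)
    initial = [reference_counts.get(s, 0) / n[s] for s in strata]
    s_w = float(sum(reference_counts.get(s, 0) for s in n))
    s_h = float(sum(1 for r in cohort_rows if r["engaged"]))
    s_w_nh = sum(w for r, w in zip(cohort_rows, initial) if not r["engaged"])
    scale = (s_w - s_h) / s_w_nh if s_w_nh > 0 else float("nan")
    final = []
    for r, w in zip(cohort_rows, initial):
        if r["engaged"]:
            final.append(1.0)
        elif s_w_nh > 0:
            final.append(w * scale)
        else:
            final.append(w)
    return initial, final, {"s_w": s_w, "s_h": s_h, "s_w_nh": s_w_nh, "scale": scale}
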