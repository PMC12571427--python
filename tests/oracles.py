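"""Independent plain-language reimplementations of both phenotype rule sets.

Deliberately written against plain dicts with naive loops and literal string
checks, sharing no code or constants with the package, so they can serve as
label-by-label oracles for the real implementations.

A patient record is a dict:
    {"labs": [(date, analyte, value)], "dxs": [(date, code)],
     "meds": [(date, ingredient, event_type)], "pregnancies": [(start, end)]}
where codes are dotless uppercase strings.
"""

import datetime as dt

CP1_OTHER_MEDS = {
    "albiglutide", "alogliptin", "chlorpropamide", "dulaglutide", "ertugliflozin",
    "exenatide", "glimepiride", "glipizide", "glyburide", "liraglutide",
    "lixisenatide", "pramlintide", "rosiglitazone", "semaglutide", "sitagliptin",
    "tolazamide", "tolbutamide", "acarbose", "canagliflozin", "dapagliflozin",
    "empagliflozin", "gliclazide", "linagliptin", "miglitol", "nateglinide",
    "pioglitazone", "repaglinide", "saxagliptin", "tirzepatide",
}

CP2_WIDENET_MEDS = {
    "exenatide", "gliclazide", "glimepiride", "glipizide", "glyburide", "insulin",
    "meglitinide", "metformin", "nateglinide", "pioglitazone", "pramlintide",
    "repaglinide", "rosiglitazone", "sitagliptin", "sulfonylurea",
    "thiazolidinediones",
}


def _is_t1_code(code):
    if code.startswith("E10"):
        return True
    return len(code) == 5 and code.startswith("250") and code[4] in "13"


def _is_t2_code(code):
    if code.startswith("E11"):
        return True
    return len(code) == 5 and code.startswith("250") and code[4] in "02"


def oracle_cp1_label(rec, year):
    lo = dt.date(year - 1, 1, 1)
    hi = dt.date(year, 12, 31)

    def in_win(d):
        return lo <= d <= hi

    def in_pregnancy(d):
        return any(s <= d <= e for s, e in rec.get("pregnancies", []))

    # diabetes step
    abnormal_dates = set()
    for d, analyte, value in rec["labs"]:
        if not in_win(d):
            continue
        if analyte == "hba1c" and float(value) >= 6.5:
            abnormal_dates.add(d)
        elif analyte == "fasting_glucose" and float(value) >= 126:
            abnormal_dates.add(d)
        elif analyte == "random_glucose" and float(value) >= 200:
            abnormal_dates.add(d)

    dx_dates = set()
    for d, code in rec["dxs"]:
        if in_win(d) and (code.startswith("250") or code.startswith("E10")
                          or code.startswith("E11") or code.startswith("E14")):
            dx_dates.add(d)

    insulin = any(
        ing == "insulin" and et == "prescribed" and in_win(d) and not in_pregnancy(d)
        for d, ing, et in rec["meds"]
    )
    other_med = any(
        ing in CP1_OTHER_MEDS and et == "prescribed" and in_win(d)
        for d, ing, et in rec["meds"]
    )

    diabetes = len(abnormal_dates) >= 2 or len(dx_dates) >= 2 or insulin or other_med
    if not diabetes:
        return "none"

    # type 1 step
    cpep = any(analyte == "c_peptide" and in_win(d) and float(v) < 0.8
               for d, analyte, v in rec["labs"])
    autoab = any(analyte == "diabetes_autoantibody" and in_win(d) and v == "positive"
                 for d, analyte, v in rec["labs"])
    strips = any(ing == "urine acetone test strips" and et == "prescribed" and in_win(d)
                 for d, ing, et in rec["meds"])
    n_t1 = sum(1 for d, c in rec["dxs"] if in_win(d) and _is_t1_code(c))
    n_t2 = sum(1 for d, c in rec["dxs"] if in_win(d) and _is_t2_code(c) and not _is_t1_code(c))
    ratio_high = n_t1 > 0 and (n_t2 == 0 or n_t1 / n_t2 > 0.5)
    glucagon = any(ing == "glucagon" and et == "prescribed" and in_win(d)
                   for d, ing, et in rec["meds"])

    t1d = (cpep or autoab or strips
           or (ratio_high and glucagon)
           or (ratio_high and not other_med))
    return "T1D" if t1d else "T2D"


def _cp2_dm_code(code):
    for prefix in ("E08", "E10", "E11", "E13"):
        if code.startswith(prefix):
            return True
    return len(code) == 5 and code.startswith("250") and code[4] in "02"


def oracle_cp2_label(rec, year, mode="or_printed"):
    lo = dt.date(year - 2, 1, 1)
    hi = dt.date(year, 12, 31)

    def in_win(d):
        return lo <= d <= hi

    # step 1: wide net
    wide = False
    for d, analyte, value in rec["labs"]:
        if not in_win(d):
            continue
        if analyte == "hba1c" and float(value) >= 6.5:
            wide = True
        elif analyte == "fasting_glucose" and float(value) >= 126:
            wide = True
        elif analyte == "random_glucose" and float(value) >= 200:
            wide = True
    if any(in_win(d) and _cp2_dm_code(c) for d, c in rec["dxs"]):
        wide = True
    if any(in_win(d) and ing in CP2_WIDENET_MEDS for d, ing, _ in rec["meds"]):
        wide = True
    if not wide:
        return "none"

    # step 2: codes only
    n_confirm = sum(1 for d, c in rec["dxs"] if in_win(d) and _cp2_dm_code(c))
    if n_confirm == 0:
        return "none"
    n_t1 = sum(1 for d, c in rec["dxs"] if in_win(d) and _is_t1_code(c))
    n_dm = sum(1 for d, c in rec["dxs"] if in_win(d) and (_cp2_dm_code(c) or _is_t1_code(c)))

    ratio_ok = n_t1 / n_dm <= 0.5
    if mode == "ratio_only":
        return "T2D" if ratio_ok else "T1D"
    other_med = any(
        in_win(d) and ing in CP2_WIDENET_MEDS and ing not in ("insulin", "metformin")
        for d, ing, _ in rec["meds"]
    )
    glucagon = any(in_win(d) and ing == "glucagon" for d, ing, _ in rec["meds"])
    t2d = ratio_ok or other_med or not glucagon
    return "T2D" if t2d else "T1D"
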