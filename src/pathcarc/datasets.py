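"""Synthetic reconstructions of the published study's summary tables.

The original 26-chemical NTP mouse study and the cross-species validation
panels are not redistributable, but their printed summaries (per-chemical
tumor calls, equivocal p-values, and the ROC operating points with named
false positives/negatives) fully determine small fixtures.  Everything in
this module is synthetic: bioassay records are solved numerically so the
poly-3 statistic reproduces the printed call for each chemical, and the
labeled-score panels are constructed so the ROC vertex inside the reported
specificity window reproduces the reported confusion lists exactly.
"""

from __future__ import annotations

from scipy import stats
from scipy.optimize import brentq

from .carcinogenicity import BioassayRecord, poly3_z
from .evaluation import LabeledScores

__all__ = [
    "MOUSE_TUMOR_CALLS",
    "EQUIVOCAL_P",
    "synthetic_mouse_bioassay",
    "mouse_operating_scores",
    "rat_operating_scores",
    "human_operating_scores",
]

#: published two-year liver tumor calls for the 26 mouse chemicals
#: ('yes' = carcinogenic, 'no' = not, 'eq' = equivocal/borderline)
MOUSE_TUMOR_CALLS = {
    "adbq": "yes", "bfur": "yes", "mecl": "yes", "macr": "yes", "napd": "yes",
    "tdpp": "yes", "tcpn": "yes", "dcbz": "yes", "pgbe": "yes", "tfel": "yes",
    "bbmp": "no", "dbet": "no", "etox": "no", "npth": "no", "vanp": "no",
    "cmph": "no", "diaz": "no", "iodo": "no", "mala": "no", "nedd": "no",
    "naac": "no", "pcnb": "no", "tfea": "no", "tcfm": "no",
    "benz": "eq", "coum": "eq",
}

#: one-sided bioassay p-values reported for the two equivocal chemicals
EQUIVOCAL_P = {"benz": 0.075, "coum": 0.084}

# mouse operating point reported in the original study
MOUSE_FALSE_POSITIVES = ["naac", "iodo", "nedd", "coum", "mala", "pcnb", "dbet"]
MOUSE_FALSE_NEGATIVES = ["adbq", "macr", "tdpp", "tfel"]

# rat operating point: named false calls; the remaining treatment ids are
# synthetic placeholders (the full treatment list is not in the main text,
# but the printed sensitivity 0.7 / specificity 0.67 with 3 FP and 3 FN
# imply 10 positives and 9 negatives)
RAT_FALSE_POSITIVES = ["APAP", "TYP", "VtC"]
RAT_FALSE_NEGATIVES = ["ESG_LOW", "SAF_LOW", "MEG_LOW"]
RAT_TRUE_POSITIVES = [f"RAT_POS_{i}" for i in range(1, 8)]
RAT_TRUE_NEGATIVES = [f"RAT_NEG_{i}" for i in range(1, 7)]

# human panel: 13 expression data sets (all positive for liver-cancer risk),
# plus gene-polymorphism sets of which only the liver set is positive
HUMAN_EXPRESSION_SETS = [
    "GDS2239", "GDS3347", "GDS3656", "GSE10356_AC", "GSE10356_HC",
    "GSE15331", "GSE15653", "GSE16415", "GSE20948_12hr", "GSE20948_18hr",
    "GSE20948_24hr", "GSE20948_48hr", "GSE23343",
]
HUMAN_SNP_SETS = [
    "snp_bladder", "snp_brain", "snp_breast", "snp_cancer", "snp_cervical",
    "snp_colorectal", "snp_endometrial", "snp_esophageal", "snp_gastric",
    "snp_head_and_neck", "snp_liver", "snp_lung", "snp_lymphoma",
    "snp_lymphoma_hodgkins", "snp_ovarian", "snp_pancreatic", "snp_prostate",
    "snp_renal", "snp_skin_non_melanoma", "snp_testicular", "snp_thyroid",
    "snp_leukemia", "snp_leukemia_childhood_all", "snp_alzheimers",
    "snp_schizophrenia",
]
HUMAN_FALSE_POSITIVES = [
    "snp_cervical", "snp_endometrial", "snp_esophageal", "snp_gastric",
    "snp_head_and_neck", "snp_lung", "snp_ovarian", "snp_testicular",
    "snp_lymphoma", "snp_lymphoma_hodgkins",
]
HUMAN_FALSE_NEGATIVES = ["GSE16415"]


def _record_for_z(chemical_id: str, z_target: float) -> BioassayRecord:
    """Solve a 50/50-arm record whose poly-3 z hits ``z_target`` exactly.

    Control incidence is fixed at 0.10; the treated proportion is found by
    root-finding, so the record is synthetic but internally consistent.
    """
    n, p_c = 50.0, 0.10

    def f(p_t):
        return poly3_z(BioassayRecord(chemical_id, n, p_t, n, p_c)) - z_target

    p_t = brentq(f, 1e-9, 1.0 - 1e-9, xtol=1e-12)
    return BioassayRecord(chemical_id, n, float(p_t), n, p_c)


def synthetic_mouse_bioassay() -> list:
    """26 synthetic bioassay records matching the printed tumor calls.

    Carcinogens get z values safely above the p = 0.01 critical value,
    non-carcinogens safely below, and the two equivocal chemicals get
    exactly their reported one-sided p-values (0.075, 0.084) — which the
    p <= 0.01 call rule maps to negative.
    """
    yes = [c for c, call in MOUSE_TUMOR_CALLS.items() if call == "yes"]
    no = [c for c, call in MOUSE_TUMOR_CALLS.items() if call == "no"]
    records = []
    for i, chem in enumerate(yes):
        records.append(_record_for_z(chem, 2.8 + 0.25 * i))
    for i, chem in enumerate(no):
        records.append(_record_for_z(chem, -1.0 + 0.2 * i))
    for chem, p in EQUIVOCAL_P.items():
        records.append(_record_for_z(chem, float(stats.norm.isf(p))))
    return records


def _operating_panel(
    false_positives: list,
    true_positives: list,
    true_negatives: list,
    false_negatives: list,
) -> LabeledScores:
    """Scores arranged so one ROC vertex reproduces the printed confusion.

    Above-threshold block: false positives outscore true positives (so no
    intermediate vertex reaches the reported sensitivity at higher
    specificity); below-threshold block: true negatives outscore false
    negatives (so the next vertex drops specificity out of the window
    before sensitivity rises).
    """
    ids, scores, labels = [], [], []

    def block(names, start, step, label):
        for k, name in enumerate(names):
            ids.append(name)
            scores.append(start - k * step)
            labels.append(label)

    block(false_positives, 0.95, 0.005, "negative")
    block(true_positives, 0.80, 0.005, "positive")
    block(true_negatives, 0.40, 0.005, "negative")
    block(false_negatives, 0.20, 0.005, "positive")
    return LabeledScores(ids, scores, labels)


def mouse_operating_scores() -> LabeledScores:
    """26-chemical panel reproducing the mouse ROC row (sens 0.6, spec 0.56).

    Labels follow the printed calls with equivocals counted negative: 10
    positives, 16 negatives; 7 named false positives, 4 false negatives.
    """
    positives = [c for c, call in MOUSE_TUMOR_CALLS.items() if call == "yes"]
    negatives = [c for c, call in MOUSE_TUMOR_CALLS.items() if call in ("no", "eq")]
    tp = [c for c in positives if c not in MOUSE_FALSE_NEGATIVES]
    tn = [c for c in negatives if c not in MOUSE_FALSE_POSITIVES]
    return _operating_panel(MOUSE_FALSE_POSITIVES, tp, tn, MOUSE_FALSE_NEGATIVES)


def rat_operating_scores() -> LabeledScores:
    """Rat panel reproducing the printed row (sens 0.7, spec 0.67)."""
    return _operating_panel(
        RAT_FALSE_POSITIVES, RAT_TRUE_POSITIVES, RAT_TRUE_NEGATIVES, RAT_FALSE_NEGATIVES
    )


def human_operating_scores() -> LabeledScores:
    """Human panel reproducing the printed row (sens 0.93, spec 0.58).

    All 13 expression sets plus the liver polymorphism set are positive
    (14); the 24 non-liver polymorphism sets are negative.
    """
    positives = HUMAN_EXPRESSION_SETS + ["snp_liver"]
    negatives = [s for s in HUMAN_SNP_SETS if s != "snp_liver"]
    tp = [s for s in positives if s not in HUMAN_FALSE_NEGATIVES]
    tn = [s for s in negatives if s not in HUMAN_FALSE_POSITIVES]
    return _operating_panel(HUMAN_FALSE_POSITIVES, tp, tn, HUMAN_FALSE_NEGATIVES)
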