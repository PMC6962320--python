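"""Published reference values of the COPDGene-derived annotated-point
cohort and of the reference CNN ensemble evaluated on it.

These printed values serve as worked-example inputs: the split arithmetic
can be exercised on the cohort's class skew without the (restricted) CT
data, and the metric identities GM = sqrt(SN*SP), BA = (SN+SP)/2 can be
audited against the reported per-class results.
"""

from __future__ import annotations

from .tissue import TissueClass as T

#: Annotated points per tissue class in the training cohort (208 subjects,
#: two reconstruction kernels per scan). The nodular count is ambiguous in
#: the source (116 vs 117); 117 is used here.
COHORT_CLASS_COUNTS = {
    T.NP: 23696,
    T.GG: 137,
    T.RETIC: 5409,
    T.NOD: 117,
    T.LINSC: 195,
    T.SUBPL: 413,
    T.PS: 3845,
    T.CL: 3613,
}

#: Number of scans contributing points per class.
COHORT_SCAN_COUNTS = {
    T.NP: 161, T.GG: 9, T.RETIC: 58, T.NOD: 7,
    T.LINSC: 8, T.SUBPL: 19, T.PS: 43, T.CL: 51,
}

#: Reported per-class test-set sizes under the published split
#: (600 cross-validation training points per class).
REFERENCE_TEST_COUNTS = {
    T.NP: 23096, T.GG: 34, T.RETIC: 4809, T.NOD: 30,
    T.LINSC: 48, T.SUBPL: 103, T.PS: 3245, T.CL: 3013,
}

REFERENCE_TRAIN_PER_CLASS = 600
REFERENCE_TRAIN_TOTAL = 4800
REFERENCE_TEST_TOTAL = 34378

#: Reported per-class sensitivity/specificity/geometric-mean/balanced
#: accuracy of the reference weighted ensemble (TPE-optimized) on its test
#: set, plus the unweighted macro averages.
REFERENCE_CLASS_METRICS = {
    T.NP: {"SN": 0.8937, "SP": 0.9649, "GM": 0.9286, "BA": 0.9293},
    T.GG: {"SN": 0.9118, "SP": 0.9907, "GM": 0.9504, "BA": 0.9512},
    T.RETIC: {"SN": 0.8064, "SP": 0.9501, "GM": 0.8753, "BA": 0.8782},
    T.NOD: {"SN": 0.9667, "SP": 0.9977, "GM": 0.9820, "BA": 0.9822},
    T.LINSC: {"SN": 0.9375, "SP": 0.9936, "GM": 0.9652, "BA": 0.9656},
    T.SUBPL: {"SN": 0.8544, "SP": 0.9907, "GM": 0.9200, "BA": 0.9225},
    T.PS: {"SN": 0.9405, "SP": 0.9861, "GM": 0.9630, "BA": 0.9633},
    T.CL: {"SN": 0.9220, "SP": 0.9810, "GM": 0.9510, "BA": 0.9515},
}

REFERENCE_MACRO_METRICS = {"SN": 0.9041, "SP": 0.9818, "GM": 0.9420, "BA": 0.9430}

#: Reported optimized fusion weights per search method, in canonical
#: ensemble member order (BCNN2D, MSTAGE_CNN2D, MCONTEXT_CNN2D, BCNN3D,
#: MSTAGE_CNN3D, BCNN2p5D, MSTAGE_CNN2p5D).
REFERENCE_WEIGHTS = {
    "RS": (0.468, 0.635, 0.285, 0.630, 0.690, 0.145, 0.645),
    "TPE": (0.682, 0.979, 0.367, 0.781, 0.980, 0.373, 0.902),
    "BO": (0.745, 1.000, 0.447, 0.849, 1.000, 0.389, 1.000),
}
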