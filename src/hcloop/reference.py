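"""Reported cohort tables used as analysis inputs.

These are the published summary counts and statistics of the study system
(optogenetic circuit-mapping cohorts and behavioral cohorts); the analyses
recompute percentages, ratios and indices from them.
"""

from __future__ import annotations

from .ephys import ConnectivityTable

#: Cells responding to, spiking to, or monosynaptically driven by
#: photostimulation of hippocampal axons, per EC layer.  Each entry is
#: (count, n_tested); denominators differ because different subsets of
#: cells entered each assay.
CONNECTIVITY_COUNTS = ConnectivityTable(
    counts={
        "EC_L5": {
            "responsive": (60, 61),
            "spiking": (13, 47),
            "monosynaptic": (18, 22),
        },
        "EC_L2/3": {
            "responsive": (49, 56),
            "monosynaptic": (9, 22),
        },
    }
)

#: Cohort-mean exploration times (s) in the novel-object-recognition test
#: phase: (novel, familiar) for the control cohort and the silenced cohort.
NOR_EXPLORATION_S = {
    "control": (37.94, 26.51),
    "silenced": (14.99, 20.54),
}

#: Cohort-median peak EPSC / IPSC amplitudes (nA) per layer.
PSC_MEDIANS_NA = {
    "EC_L5": {"epsc": -0.83, "ipsc": 1.61},
    "EC_L2/3": {"epsc": -0.27, "ipsc": 1.43},
}

#: ITDP potentiation folds by layer and pathway (cohort means).
ITDP_FOLDS = {
    ("EC_L2/3", "sensory"): 1.75,
    ("EC_L2/3", "hippocampal"): 0.93,
    ("EC_L5", "sensory"): 1.12,
    ("EC_L5", "hippocampal"): 1.40,
}
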