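"""Reference data presets for the whey-hydrolysate / casein comparison study.

The package was built around a four-product crossover study: three whey
protein hydrolysates (WPH) differing in degree of hydrolysis (DH; the
percentage of cleaved peptide bonds — 48, 27 and 23 % here) and an intact
casein reference, each given as a 500 mL drink containing 20 g protein to
five fasted men, with blood sampled pre-ingestion and at 10, 20, 30, 45,
60, 90 and 120 min. The same four proteins were fed to growing rats in a
5-day nitrogen-balance assay (10 g dry matter and 150 mg N per day).

This module collects the published summary numbers of that study — the
supplement amino-acid compositions, the rat-assay true digestibility and
biological value, and the fitted plasma-appearance rate constants k1 —
plus the FAO/WHO child (3-10 y) essential-amino-acid reference pattern
used for PDCAAS scoring. They serve as scoring inputs, generator defaults
and cross-check values; raw individual-level data were never published, so
everything subject-level in this package is simulated (see ``simulate``).
"""

from __future__ import annotations

from .kinetics import KineticParams

SUPPLEMENTS = ("High DH", "Medium DH", "Low DH", "Casein")

#: Amino-acid composition of each supplement, mg AA per g total protein
#: (the published table prints % of total protein; x10 converts to mg/g).
AMINO_ACID_PROFILES: dict[str, dict[str, float]] = {
    "High DH": {
        "leu": 162.0, "ile": 61.0, "val": 72.0, "lys": 71.0, "met": 19.0,
        "phe": 54.0, "thr": 69.0, "trp": 25.0, "ala": 74.0, "arg": 25.0,
        "asp": 65.0, "cys": 9.0, "glu": 94.0, "gly": 25.0, "his": 23.0,
        "pro": 17.0, "ser": 67.0, "tyr": 69.0,
    },
    "Medium DH": {
        "leu": 80.0, "ile": 53.0, "val": 48.0, "lys": 97.0, "met": 17.0,
        "phe": 22.0, "thr": 71.0, "trp": 10.0, "ala": 45.0, "arg": 21.0,
        "asp": 113.0, "cys": 22.0, "glu": 188.0, "gly": 17.0, "his": 17.0,
        "pro": 65.0, "ser": 45.0, "tyr": 71.0,
    },
    "Low DH": {
        "leu": 98.0, "ile": 55.0, "val": 52.0, "lys": 88.0, "met": 20.0,
        "phe": 30.0, "thr": 67.0, "trp": 16.0, "ala": 48.0, "arg": 22.0,
        "asp": 104.0, "cys": 23.0, "glu": 167.0, "gly": 19.0, "his": 17.0,
        "pro": 59.0, "ser": 49.0, "tyr": 67.0,
    },
    "Casein": {
        "leu": 92.0, "ile": 48.0, "val": 63.0, "lys": 78.0, "met": 27.0,
        "phe": 49.0, "thr": 40.0, "trp": 12.0, "ala": 30.0, "arg": 33.0,
        "asp": 69.0, "cys": 5.0, "glu": 211.0, "gly": 18.0, "his": 28.0,
        "pro": 105.0, "ser": 54.0, "tyr": 40.0,
    },
}

#: Rat-assay true digestibility (%, mean over 5 animals) per supplement.
TRUE_DIGESTIBILITY: dict[str, float] = {
    "High DH": 97.0, "Medium DH": 97.0, "Low DH": 94.0, "Casein": 96.0,
}

#: Rat-assay biological value (%, mean over 5 animals) per supplement.
BIOLOGICAL_VALUE: dict[str, float] = {
    "High DH": 58.0, "Medium DH": 78.0, "Low DH": 87.0, "Casein": 69.0,
}

#: Published plasma-appearance rate constants k1 (concentration/min) with
#: 95 % confidence intervals, per analyte aggregate and supplement.
K1_ESTIMATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "TAA": {
        "High DH": (0.0585, 0.0454, 0.0754),
        "Medium DH": (0.0594, 0.0459, 0.0768),
        "Low DH": (0.0560, 0.0429, 0.0732),
        "Casein": (0.0194, 0.0129, 0.0291),
    },
    "EAA": {
        "High DH": (0.0384, 0.0264, 0.0559),
        "Medium DH": (0.0338, 0.0231, 0.0495),
        "Low DH": (0.0331, 0.0221, 0.0497),
        "Casein": (0.0114, 0.0073, 0.0178),
    },
    "Leucine": {
        "High DH": (0.0111, 0.0072, 0.0169),
        "Medium DH": (0.0076, 0.0049, 0.0117),
        "Low DH": (0.0072, 0.0045, 0.0115),
        "Casein": (0.0024, 0.0015, 0.0038),
    },
}

#: EAA reference patterns for PDCAAS scoring, mg per g protein, keyed by
#: the nine scoring categories. Patterns are config data, never hard-coded
#: into the scoring math.
REFERENCE_PATTERNS: dict[str, dict[str, float]] = {
    "fao_who_2007_child_3_10": {
        "his": 15.0, "ile": 30.0, "leu": 61.0, "lys": 48.0,
        "met+cys": 23.0, "phe+tyr": 41.0, "thr": 25.0, "trp": 6.6,
        "val": 40.0,
    },
}

#: Default true kinetic parameters for the trial simulator, per supplement.
#: k1 values are the published TAA point estimates; k3, x0 and y0 were
#: never published and are plausible fills chosen to give curves of the
#: magnitude seen in the study (fasting TAA ~2.6 mmol/L; whey plateau
#: ~4.4 mmol/L reached while the stomach empties over ~1 h; casein
#: emptying time ~200 min) — they are NOT study estimates.
DEFAULT_TRIAL_PARAMS: dict[str, KineticParams] = {
    "High DH": KineticParams(k1=0.0585, k3=0.0133, x0=3.50, y0=2.6),
    "Medium DH": KineticParams(k1=0.0594, k3=0.0133, x0=3.56, y0=2.6),
    "Low DH": KineticParams(k1=0.0560, k3=0.0133, x0=3.36, y0=2.6),
    "Casein": KineticParams(k1=0.0194, k3=0.0060, x0=3.88, y0=2.6),
}

#: Nitrogen-balance assay constants: metabolic faecal N per g dry matter,
#: endogenous urinary N per day (growing rat), and the N-to-protein factor.
N_METABOLIC_RATE = 1.01   # mg N / g DM
N_ENDOGENOUS_RATE = 15.2  # mg N / day
N_TO_PROTEIN = 6.38

#: Daily ration of the balance assay and its duration.
BALANCE_DM_PER_DAY = 10.0   # g DM / day
BALANCE_N_PER_DAY = 150.0   # mg N / day
BALANCE_DAYS = 5

#: Sampling grid of the human trial, minutes after complete ingestion
#: (the -5 min pre sample is recorded as the t = 0 baseline).
TRIAL_TIME_GRID = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)

#: The arm excluded from the study's analyses (a protocol deviation:
#: the subject drank water after ingesting the Low DH supplement).
EXCLUDED_ARM = (2, "Low DH")
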