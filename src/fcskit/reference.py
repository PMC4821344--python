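"""Published EGFP-FMBP-1 diffusion parameter sets.

Mean fitted parameters for EGFP-tagged FMBP-1 (the Bombyx mori
fibroin-modulator-binding protein) and control EGFP measured by FCS in
posterior silk gland (PSG) and HeLa cell nuclei.  Fractions are in
percent, diffusion times in seconds; ``bleach`` records whether the
construct showed observable photobleaching.  These sets serve as
realistic ground truths for the synthetic-data generator and as inputs
to the derived-quantity arithmetic.
"""

#: Measurements in posterior silk gland cell nuclei.
PSG = {
    "egfp": {"F": (100.0,), "tau": (266.7e-6,), "bleach": False, "n": 13},
    "wild_type": {
        "F": (45.1, 41.4, 13.5),
        "tau": (343.2e-6, 3.28e-3, 98.2e-3),
        "bleach": True,
        "n": 29,
    },
    "r9a_rep3": {
        "F": (76.9, 23.1),
        "tau": (339.8e-6, 5.99e-3),
        "bleach": False,
        "n": 16,
    },
}

#: Measurements in HeLa cell nuclei (subset).
HELA = {
    "egfp": {"F": (100.0,), "tau": (278.2e-6,), "bleach": False, "n": 15},
    "wild_type": {
        "F": (33.9, 52.8, 13.3),
        "tau": (335.1e-6, 2.43e-3, 112.1e-3),
        "bleach": True,
        "n": 27,
    },
    "r9a_rep3": {
        "F": (40.9, 59.1),
        "tau": (354.8e-6, 3.20e-3),
        "bleach": False,
        "n": 15,
    },
}

#: Molecular mass of monomeric EGFP-FMBP-1 (kDa).
FMBP1_EGFP_MONOMER_KDA = 51.2

#: Reported per-measurement-averaged diffusion coefficients (um^2/s) of
#: the 2nd and 3rd wild-type components in PSG cells.  These are means
#: of per-cell D values, not omega^2/(4 tau_mean) of the mean diffusion
#: times (Jensen gap on a dispersed tau sample).
PSG_WT_D2_MEAN = 3.62
PSG_WT_D3_MEAN = 0.19

#: FMBP-1 recognition-site consensus (IUPAC) near the fibroin H-chain gene.
FMBP1_MOTIF = "ATNTWTNTA"

#: FRAP recovery half-time (s) of chromatin-bound wild-type EGFP-FMBP-1.
WT_FRAP_T_HALF = 20.0
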