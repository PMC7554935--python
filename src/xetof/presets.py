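"""Named parameter presets.

Kinetics values are literature-derived physiologic defaults for dissolved
:sup:`129`Xe in the adult human brain (gray-matter perfusion about
0.55 mL/mL/min, white matter about 0.22 mL/mL/min, partition coefficient
about 0.9, blood T1 about 8 s, tissue T1 about 16 s at 3 T), not quantities
measured by this package.

Several published TOF-delay triples exist for the in vivo protocol and they
are not mutually consistent; every variant is shipped and none is canonical.
The ``linear_regime`` triple keeps all delays inside the short-time window
where the linearized uptake model is accurate and is the default for the
synthetic validation studies.
"""

from __future__ import annotations

from .kinetics import KineticsParams

#: TOF recovery delay triples (s) by protocol name.
TOF_DELAY_PRESETS: dict[str, tuple[float, float, float]] = {
    "invivo_axial": (2.5, 6.7, 7.1),
    "invivo_sagittal": (1.0, 6.5, 7.1),
    "visual": (1.0, 6.5, 8.0),
    "motor": (2.5, 6.8, 7.1),
    "linear_regime": (0.1, 0.2, 0.3),
}

#: Tissue kinetics presets (see module docstring for provenance).
KINETICS_PRESETS: dict[str, KineticsParams] = {
    "gray_matter": KineticsParams(
        f=0.55, lam=0.9, t1_blood=8.0, t1_tissue=16.0, m_a0=100.0
    ),
    "white_matter": KineticsParams(
        f=0.22, lam=0.9, t1_blood=8.0, t1_tissue=16.0, m_a0=100.0
    ),
}

#: Flow-phantom TOF sampling: 20 recovery times starting at 200 ms with a
#: 100 ms step.  (A 200..2000 ms range holds only 19 such times; the count
#: of 20 is kept and the grid ends at 2.1 s.)
FLOW_TAU_GRID_S: tuple[float, ...] = tuple(
    round(0.2 + 0.1 * i, 10) for i in range(20)
)

#: Syringe-pump flow rates used for the in vitro study, mL/min.
FLOW_RATES_ML_MIN: tuple[float, ...] = (5.0, 6.0, 7.0, 10.0)
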