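"""qPCR summary formulas used for sample quality control.

``signal_to_noise`` implements, verbatim, the published DNase-qPCR
summary 2^[(DHS_genomic - DHS_DNase) / NegAvg], where NegAvg averages the
three negative-control ΔCT values.  Note the unusual division of a ΔCT
by an average ΔCT inside the exponent — this differs from the
conventional 2^(ΔΔCT) = 2^(ΔCT_target - ΔCT_background), which is
available via ``conventional=True``.  The verbatim form is the default
so reported values match the published quality-control tables.
"""

from __future__ import annotations

from typing import Sequence


def signal_to_noise(dhs_genomic: float, dhs_dnase: float,
                    neg_genomic: Sequence[float],
                    neg_dnase: Sequence[float],
                    conventional: bool = False) -> float:
    """DNase-qPCR signal-to-noise from CT values.

    ``neg_genomic`` / ``neg_dnase`` are the CTs of the three negative
    control regions on genomic and DNase-digested template.
    """
    if len(neg_genomic) != 3 or len(neg_dnase) != 3:
        raise ValueError("exactly 3 negative control regions are expected")
    neg_avg = sum(g - d for g, d in zip(neg_genomic, neg_dnase)) / 3.0
    dhs_delta = dhs_genomic - dhs_dnase
    if conventional:
        return 2.0 ** (dhs_delta - neg_avg)
    if neg_avg == 0:
        raise ValueError("NegAvg is zero; signal-to-noise undefined")
    return 2.0 ** (dhs_delta / neg_avg)


def percent_input(ct_chip: float, ct_input: float,
                  chip_initial_vol: float, chip_final_vol: float,
                  input_initial_vol: float, input_final_vol: float) -> float:
    """ChIP-qPCR percent input with volume correction:
    [100 / 2^(CT_chip - CT_input)] x (chip final x input initial)
    / (chip initial x input final)."""
    for v in (chip_initial_vol, chip_final_vol, input_initial_vol,
              input_final_vol):
        if v <= 0:
            raise ValueError("volumes must be positive")
    return (100.0 / 2.0 ** (ct_chip - ct_input)) \
        * (chip_final_vol * input_initial_vol) \
        / (chip_initial_vol * input_final_vol)
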