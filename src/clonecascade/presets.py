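"""Named parameter sets.

The human hematopoiesis preset uses the widely adopted compartmental
estimates for adult humans: roughly 400 actively contributing hematopoietic
stem cells dividing about once per year, a constant differentiation
probability of 0.85, no cell death, and division rates increasing by a
factor 1.26 per differentiation stage.  Thirty-one downstream stages size
the hierarchy so that compartment 31 represents the circulating blood cells
and the marrow output reaches the order of 10^11 cells per day.

The PIG-A mutant preset shares the healthy rates and zero death probability
(PIG-A loss is selectively neutral in vivo) but has a slightly lower
differentiation probability of 0.765 in every compartment, which lets a
single founder clone transiently reach the frequencies observed by flow
cytometry in healthy adults before being washed out.
"""

from __future__ import annotations

from .model import CompartmentModel

__all__ = [
    "human_hematopoiesis",
    "piga_mutant",
    "HEMATOPOIESIS_EPS",
    "HEMATOPOIESIS_RATE_RATIO",
    "HEMATOPOIESIS_STEM_COUNT",
    "HEMATOPOIESIS_STEM_RATE",
    "HEMATOPOIESIS_K",
    "PIGA_MUTANT_EPS",
    "CIRCULATING_COMPARTMENT",
]

HEMATOPOIESIS_EPS = 0.85
HEMATOPOIESIS_RATE_RATIO = 1.26
HEMATOPOIESIS_STEM_COUNT = 400.0
HEMATOPOIESIS_STEM_RATE = 1.0  # divisions per stem cell per year
HEMATOPOIESIS_K = 31
CIRCULATING_COMPARTMENT = 31

PIGA_MUTANT_EPS = 0.765


def human_hematopoiesis(n_compartments: int = HEMATOPOIESIS_K) -> CompartmentModel:
    """Adult human hematopoiesis with r_k = 1.26**k per year."""
    return CompartmentModel.constant(
        n_compartments,
        eps=HEMATOPOIESIS_EPS,
        d=0.0,
        r1=HEMATOPOIESIS_RATE_RATIO,
        rate_ratio=HEMATOPOIESIS_RATE_RATIO,
        stem_count=HEMATOPOIESIS_STEM_COUNT,
        stem_rate=HEMATOPOIESIS_STEM_RATE,
    )


def piga_mutant(
    n_compartments: int = HEMATOPOIESIS_K, eps: float = PIGA_MUTANT_EPS
) -> CompartmentModel:
    """PIG-A mutant lineage: healthy rates, reduced differentiation probability."""
    return human_hematopoiesis(n_compartments).with_(
        diff_prob=[eps] * n_compartments
    )
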