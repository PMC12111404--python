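"""Yoon connection-weight relative importance of the MLP inputs.

For a single-output network the signed relative importance of input i is

    RI_i (%) = 100 * sum_k w_ih[k, i] * w_ho[k]
                   / sum_i' | sum_k w_ih[k, i'] * w_ho[k] |

Biases are excluded from both sums. The sign is meaningful: a negative RI
means increasing that input decreases the predicted output. Absolute values
sum to 100 by construction. RI is computed on the standardized-scale
network, where the inputs are comparably scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlp import MLPParams

__all__ = ["RelativeImportance", "yoon_ri", "rank_agreement", "INPUT_NAMES"]

INPUT_NAMES = ("etoh", "sl", "time")


@dataclass(frozen=True)
class RelativeImportance:
    ri: np.ndarray                 # signed percentages, one per input
    input_names: tuple[str, ...]
    rank_order: tuple[str, ...]    # by |ri| descending, ties by declaration order

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.input_names, self.ri)}

    def to_dict(self) -> dict:
        return {"ri_percent": self.as_dict(), "rank_order": list(self.rank_order)}


def yoon_ri(
    params: MLPParams, input_names: tuple[str, ...] = INPUT_NAMES
) -> RelativeImportance:
    """Signed Yoon relative importance from the trained weight matrices.

    Raises ValueError when every input's connection-weight products cancel
    (zero denominator), rather than returning NaN.
    """
    if len(input_names) != params.n_in:
        raise ValueError(
            f"{params.n_in}-input network needs {params.n_in} names, "
            f"got {len(input_names)}"
        )
    # numerator_i = sum_k w_ih[k, i] * w_ho[k]
    num = params.w_ho @ params.w_ih
    den = float(np.sum(np.abs(num)))
    if den == 0.0:
        raise ValueError(
            "Yoon denominator is zero: all input-hidden-output weight products cancel"
        )
    ri = 100.0 * num / den
    # stable argsort keeps declaration order on |ri| ties
    order = np.argsort(-np.abs(ri), kind="stable")
    return RelativeImportance(
        ri=ri,
        input_names=tuple(input_names),
        rank_order=tuple(input_names[i] for i in order),
    )


def rank_agreement(ri: RelativeImportance, reference_order) -> bool:
    """True iff the |RI|-descending order equals ``reference_order``.

    Ties in |RI| are broken by input declaration order (stable sort), so a
    tied pair agrees with the reference only when the reference lists it in
    declaration order too.
    """
    reference_order = tuple(reference_order)
    if set(reference_order) != set(ri.input_names) or len(reference_order) != len(
        ri.input_names
    ):
        raise ValueError(
            f"reference labels {reference_order} do not match inputs {ri.input_names}"
        )
    return ri.rank_order == reference_order
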