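"""Embedded-chain transition estimation and the semi-Markov log-likelihood.

A semi-Markov chain (SMC) describes a TDS record by (a) the initial
attribute distribution, (b) the embedded transition matrix between
attributes -- self-transitions are impossible because a dominance spell
only ends when the attribute changes -- augmented with a terminal STOP
column for the end of the experiment, and (c) the sojourn (dominance
duration) distributions handled in :mod:`tdsmc.models`.  Both probability
components are estimated by relative frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import AttributeScheme, TDSDataError, TDSSequence

__all__ = ["TransitionEstimate", "estimate_transitions", "smc_loglik"]

STOP = "STOP"


@dataclass
class TransitionEstimate:
    """Frequency estimates of the embedded chain with a STOP state.

    ``trans`` is J x (J+1); column J is STOP.  Probabilities equal
    counts / row totals exactly; attributes never observed as a source have
    an all-zero row and are listed in ``zero_rows``.
    """

    initial: np.ndarray
    trans: np.ndarray
    counts: np.ndarray
    initial_counts: np.ndarray
    labels: tuple[str, ...]
    zero_rows: tuple[str, ...]

    @property
    def n_attributes(self) -> int:
        return len(self.labels)

    def initial_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"attribute": self.labels, "count": self.initial_counts, "probability": self.initial}
        )

    def trans_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.trans, index=list(self.labels), columns=list(self.labels) + [STOP])
        frame.index.name = "from"
        return frame

    def to_csv(self, initial_path: str | Path, trans_path: str | Path) -> None:
        self.initial_frame().to_csv(initial_path, index=False)
        self.trans_frame().to_csv(trans_path)

    def to_dot(
        self, trans_threshold: float = 0.20, io_threshold: float = 0.10
    ) -> str:
        """Graphviz DOT rendering of the transition diagram.

        Display thresholds only hide edges in the drawing (transitions below
        ``trans_threshold``, START/STOP edges below ``io_threshold``); the
        stored probabilities are unaffected.
        """
        lines = [
            "digraph tds {",
            "  rankdir=LR;",
            '  START [shape=plaintext]; STOP [shape=plaintext];',
        ]
        for label in self.labels:
            lines.append(f'  "{label}" [shape=ellipse];')
        for j, p in enumerate(self.initial):
            if p >= io_threshold:
                lines.append(f'  START -> "{self.labels[j]}" [label="{p:.2f}"];')
        for j in range(self.n_attributes):
            for k in range(self.n_attributes):
                p = self.trans[j, k]
                if p >= trans_threshold:
                    lines.append(
                        f'  "{self.labels[j]}" -> "{self.labels[k]}" [label="{p:.2f}"];'
                    )
            p_stop = self.trans[j, -1]
            if p_stop >= io_threshold:
                lines.append(f'  "{self.labels[j]}" -> STOP [label="{p_stop:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


def estimate_transitions(
    sequences: Sequence[TDSSequence], scheme: AttributeScheme
) -> TransitionEstimate:
    """Relative-frequency estimates of initial and embedded transition probabilities.

    ``initial[j]`` is the fraction of panelists whose first spell is
    attribute j; ``trans[j, k]`` is the fraction of attribute-j spells
    immediately followed by k, where "followed by the end of the
    experiment" counts toward the STOP column.
    """
    if not sequences:
        raise TDSDataError("no sequences given")
    J = scheme.n_attributes
    counts = np.zeros((J, J + 1), dtype=int)
    initial_counts = np.zeros(J, dtype=int)
    for seq in sequences:
        attrs = [a for a, _ in seq.runs]
        initial_counts[attrs[0]] += 1
        for a, b in zip(attrs[:-1], attrs[1:]):
            counts[a, b] += 1
        counts[attrs[-1], J] += 1
    row_totals = counts.sum(axis=1)
    trans = np.zeros_like(counts, dtype=float)
    nonzero = row_totals > 0
    trans[nonzero] = counts[nonzero] / row_totals[nonzero, None]
    zero_rows = tuple(scheme.labels[j] for j in np.flatnonzero(~nonzero))
    return TransitionEstimate(
        initial=initial_counts / len(sequences),
        trans=trans,
        counts=counts,
        initial_counts=initial_counts,
        labels=scheme.labels,
        zero_rows=zero_rows,
    )


def smc_loglik(
    sequences: Sequence[TDSSequence],
    estimate: TransitionEstimate,
    log_duration_pmf: Callable[[str, int, int], float],
) -> float:
    """Full semi-Markov log-likelihood of the observed sequences.

    The chain factorizes as initial attribute x sojourn durations x
    embedded transitions x the terminal STOP transition, with durations
    independent of the next state.  ``log_duration_pmf(panelist_id,
    attribute_index, duration)`` supplies the sojourn term; the final spell
    is treated as fully observed (the panelist clicks finish when dominance
    ends), not censored.

    If any observed event has probability zero under ``estimate``, returns
    ``-inf`` after warning with the offending events.
    """
    J = estimate.n_attributes
    total = 0.0
    offenders: list[str] = []
    for seq in sequences:
        attrs = [a for a, _ in seq.runs]
        p0 = estimate.initial[attrs[0]]
        if p0 <= 0.0:
            offenders.append(
                f"initial({estimate.labels[attrs[0]]}) for panelist {seq.panelist_id!r}"
            )
        else:
            total += np.log(p0)
        for attr, dur in seq.runs:
            total += log_duration_pmf(seq.panelist_id, attr, dur)
        steps = list(zip(attrs[:-1], attrs[1:])) + [(attrs[-1], J)]
        for a, b in steps:
            p = estimate.trans[a, b]
            if p <= 0.0:
                target = STOP if b == J else estimate.labels[b]
                offenders.append(
                    f"trans({estimate.labels[a]} -> {target}) for panelist {seq.panelist_id!r}"
                )
            else:
                total += np.log(p)
    if offenders:
        warnings.warn(
            "zero-probability events in SMC likelihood: " + "; ".join(offenders),
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    return float(total)
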