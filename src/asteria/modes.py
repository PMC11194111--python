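"""Taxonomy of pairwise interaction modes and complex-level aggregation.

Each reported interaction is characterised by the signs of the two refit
main effects (beta_j, beta_k) and of the interaction coefficient theta_jk.
Binding (positive) is coded ``b``, repulsion (negative) ``r``, giving six
modes from the eight sign combinations:

===============  ======================================  =============
direction code   meaning                                 major mode
===============  ======================================  =============
b+b+b            both bind, combination super-additive   synergy
r+r+r            both repel, combination super-repelled  synergy
b+b+r            both bind, combination sub-additive     antagonism
r+r+b            both repel, combination attenuated      antagonism
b+r+b            opposed mains, combination binds        conflict
b+r+r            opposed mains, combination repels       conflict
===============  ======================================  =============

In conflict modes the pair is re-ordered so the binding modification comes
first (the two opposed-main sign combinations collapse onto one label).
Classification uses the refit (unpenalised) coefficients of the final
model, not the shrunken path coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ModeLabel", "ComplexProfile", "classify_mode", "aggregate_complex_probabilities"]


@dataclass(frozen=True)
class ModeLabel:
    pair: tuple[str, str]
    beta_j: float
    beta_k: float
    theta_jk: float
    major: str  # synergy | antagonism | conflict
    direction_code: str
    description: str


def classify_mode(
    beta_j: float, beta_k: float, theta_jk: float, pair: tuple[str, str] = ("j", "k")
) -> ModeLabel:
    """Classify one interaction by the signs of its three refit coefficients.

    All three inputs must be nonzero (strong hierarchy guarantees this for
    any reported interaction); a zero input is a contract violation.
    """
    if beta_j == 0 or beta_k == 0 or theta_jk == 0:
        raise ValueError("classify_mode requires nonzero beta_j, beta_k and theta_jk")
    cj = "b" if beta_j > 0 else "r"
    ck = "b" if beta_k > 0 else "r"
    ct = "b" if theta_jk > 0 else "r"
    if cj == ck:
        major = "synergy" if ct == cj else "antagonism"
        code = f"{cj}+{ck}+{ct}"
        what = {
            "synergy": "combination exceeds the sum of the individual effects",
            "antagonism": "combination falls short of the sum of the individual effects",
        }[major]
        return ModeLabel(pair, beta_j, beta_k, theta_jk, major, code, f"{major}: {what}")
    # opposed main effects: canonicalise binder-first so the code is unique
    if cj == "r":
        pair = (pair[1], pair[0])
        beta_j, beta_k = beta_k, beta_j
    code = f"b+r+{ct}"
    dom = "binding" if ct == "b" else "repulsion"
    return ModeLabel(
        pair, beta_j, beta_k, theta_jk, "conflict", code, f"conflict, dominated by {dom}"
    )


@dataclass
class ComplexProfile:
    """Mean interaction selection probabilities over a protein complex."""

    complex_name: str
    members: list[str]
    mean_pi: pd.Series
    edges: list[tuple[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "complex": self.complex_name,
                "pair": [p for p, _ in self.edges],
                "mean_pi": [v for _, v in self.edges],
            }
        )


def aggregate_complex_probabilities(
    profiles: dict[str, pd.Series],
    membership: dict[str, list[str]],
    cutoff: float = 0.2,
) -> list[ComplexProfile]:
    """Average per-protein selection probabilities of interaction pairs over
    user-supplied complexes; edges above ``cutoff`` are retained (suitable
    for Sankey-style export).

    ``profiles`` maps protein id to a pi_hat Series (a
    :class:`~asteria.cpss.StabilityProfile` ``pi_hat`` attribute works);
    only interaction features (labels containing ':') are aggregated.
    Unknown members are skipped with a warning.
    """
    out = []
    for cname, members in membership.items():
        known = [m for m in members if m in profiles]
        missing = [m for m in members if m not in profiles]
        if missing:
            warnings.warn(f"complex {cname!r}: no stability profile for {missing}; skipped",
                          stacklevel=2)
        if not known:
            continue
        series = []
        for m in known:
            s = profiles[m]
            if hasattr(s, "pi_hat"):
                s = s.pi_hat
            series.append(s[[lab for lab in s.index if ":" in lab]])
        mat = pd.concat(series, axis=1)
        mean_pi = mat.mean(axis=1)
        edges = [
            (lab, float(v))
            for lab, v in mean_pi.sort_values(ascending=False).items()
            if v > cutoff
        ]
        out.append(ComplexProfile(cname, known, mean_pi, edges))
    return out
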