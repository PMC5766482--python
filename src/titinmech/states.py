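"""Domain state space and allowed transitions.

An Ig domain is described by a (fold, redox) pair.  The redox coordinate
tracks which disulfide of the CysB/CysF/CysG triad (if any) is formed:

* ``RED``   -- all three cysteines free (fully reduced domain)
* ``SS_BG`` -- the native, buried CysB-CysG disulfide
* ``SS_BF`` -- the classical CysB-CysF disulfide (isomerization product)
* ``SS_FG`` -- the CysF-CysG disulfide (isomerization product)

Chemistry on the disulfide (isomerization, reduction by Tcep) is only
possible once the domain is mechanically unfolded, because the triad is
buried in the hydrophobic core of the folded state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Fold(enum.Enum):
    FOLDED = "folded"
    UNFOLDED = "unfolded"


class Redox(enum.Enum):
    RED = "red"
    SS_BG = "ss_bg"
    SS_BF = "ss_bf"
    SS_FG = "ss_fg"


@dataclass(frozen=True)
class DomainState:
    fold: Fold
    redox: Redox

    def __str__(self) -> str:  # compact labels for event logs
        return f"{self.fold.value}:{self.redox.value}"


# Convenience singletons
FOLDED_RED = DomainState(Fold.FOLDED, Redox.RED)
FOLDED_BG = DomainState(Fold.FOLDED, Redox.SS_BG)
FOLDED_BF = DomainState(Fold.FOLDED, Redox.SS_BF)
FOLDED_FG = DomainState(Fold.FOLDED, Redox.SS_FG)
UNFOLDED_RED = DomainState(Fold.UNFOLDED, Redox.RED)
UNFOLDED_BG = DomainState(Fold.UNFOLDED, Redox.SS_BG)
UNFOLDED_BF = DomainState(Fold.UNFOLDED, Redox.SS_BF)
UNFOLDED_FG = DomainState(Fold.UNFOLDED, Redox.SS_FG)


class TransitionKind(enum.Enum):
    UNFOLD = "unfold"
    REFOLD = "refold"
    ISOMERIZE = "isomerize"
    REDUCE = "reduce"


@dataclass(frozen=True)
class Transition:
    """A directed edge of the kinetic scheme."""

    kind: TransitionKind
    before: DomainState
    after: DomainState

    @property
    def label(self) -> str:
        return f"{self.kind.value}:{self.before.redox.value}->{self.after.redox.value}"


def _edges() -> list[Transition]:
    out: list[Transition] = []
    for rx in Redox:
        out.append(Transition(TransitionKind.UNFOLD,
                              DomainState(Fold.FOLDED, rx),
                              DomainState(Fold.UNFOLDED, rx)))
        out.append(Transition(TransitionKind.REFOLD,
                              DomainState(Fold.UNFOLDED, rx),
                              DomainState(Fold.FOLDED, rx)))
    # isomerization: CysF attacks the B-G disulfide, only in the unfolded state
    out.append(Transition(TransitionKind.ISOMERIZE, UNFOLDED_BG, UNFOLDED_BF))
    out.append(Transition(TransitionKind.ISOMERIZE, UNFOLDED_BG, UNFOLDED_FG))
    # intermolecular reduction by Tcep, only in the unfolded state
    for rx in (Redox.SS_BG, Redox.SS_BF, Redox.SS_FG):
        out.append(Transition(TransitionKind.REDUCE,
                              DomainState(Fold.UNFOLDED, rx), UNFOLDED_RED))
    return out


ALLOWED_TRANSITIONS: tuple[Transition, ...] = tuple(_edges())
_ALLOWED_BY_PAIR = {(t.before, t.after): t for t in ALLOWED_TRANSITIONS}

# optional reverse isomerization edges (re-formation of the B-G disulfide);
# disabled by default in the kinetics, but the bookkeeping knows about them
REISOMERIZATION_TRANSITIONS: tuple[Transition, ...] = (
    Transition(TransitionKind.ISOMERIZE, UNFOLDED_BF, UNFOLDED_BG),
    Transition(TransitionKind.ISOMERIZE, UNFOLDED_FG, UNFOLDED_BG),
)


def transition_between(before: DomainState, after: DomainState) -> Transition:
    """Return the allowed transition for a state pair, or raise ``ValueError``."""
    try:
        return _ALLOWED_BY_PAIR[(before, after)]
    except KeyError:
        raise ValueError(
            f"transition {before} -> {after} is not allowed by the kinetic scheme"
        ) from None
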