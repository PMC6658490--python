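"""GOR-I (Garnier-Osguthorpe-Robson) four-state secondary-structure prediction.

GOR-I scores each residue position i for each conformational state s
(helix, sheet, turn, coil) as a sum of directional information values
I_s(r, d) over the 17-residue window d in [-8, +8]: the residue at i + d
contributes according to its identity r and its offset d. The state call is
the argmax, after subtracting a per-state decision constant (default 0),
with a fixed tie-break order helix > sheet > turn > coil. State fractions
(percent of residues called per state) are the downstream quantity: for
spidroins the percent of predicted beta-turns tracks the proline/glycine-
rich GPGX-family motif content that is linked to silk extensibility.

The bundled table (``data/gor_tables_synthetic.tsv``) is SYNTHETIC: it has
the exact GOR-I structure (4 states x 20 residues x 17 offsets, values in
centinats) but its values are constructed from canonical residue
conformational propensities with a distance-tapered window, not transcribed
from the originally published tables. Predictions are therefore
qualitatively GOR-like (poly-alanine reads helical, GPG-rich repeats
turn-rich) and fully deterministic, but absolute fractions are not
comparable with historical GOR-I outputs. :func:`build_synthetic_tables`
regenerates the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

STATES = ("helix", "sheet", "turn", "coil")
OFFSETS = tuple(range(-8, 9))
RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Base conformational information per (state, residue), centinats.
#: Positive favours the state. Authored from canonical propensity scales
#: (helix formers E/A/L/M, sheet formers V/I/Y/C/W/F, turn formers P/G/N/D/S).
_BASE_INFO: dict[str, dict[str, int]] = {
    "helix": {
        "A": 35, "C": -15, "D": 5, "E": 40, "F": 10, "G": -40, "H": 10,
        "I": 5, "K": 15, "L": 30, "M": 25, "N": -20, "P": -60, "Q": 20,
        "R": 0, "S": -15, "T": -10, "V": -5, "W": 5, "Y": -20,
    },
    "sheet": {
        "A": -10, "C": 25, "D": -30, "E": -30, "F": 25, "G": -20, "H": -10,
        "I": 40, "K": -15, "L": 15, "M": 10, "N": -20, "P": -40, "Q": -10,
        "R": -5, "S": -15, "T": 15, "V": 40, "W": 25, "Y": 30,
    },
    "turn": {
        "A": -30, "C": 10, "D": 30, "E": -20, "F": -25, "G": 40, "H": -10,
        "I": -40, "K": 5, "L": -35, "M": -25, "N": 35, "P": 45, "Q": 0,
        "R": -5, "S": 25, "T": 0, "V": -40, "W": -5, "Y": 10,
    },
    "coil": {
        "A": -5, "C": 0, "D": 10, "E": -10, "F": -15, "G": 20, "H": -5,
        "I": -20, "K": 5, "L": -20, "M": -15, "N": 10, "P": 25, "Q": 0,
        "R": 0, "S": 15, "T": 10, "V": -15, "W": -10, "Y": -5,
    },
}

#: Window half-widths per state: helix/sheet propagate influence further
#: along the chain than the locally determined turn/coil states.
_TAPER_SPAN = {"helix": 9, "sheet": 9, "turn": 5, "coil": 5}


class GorError(ValueError):
    pass


def build_synthetic_tables() -> pd.DataFrame:
    """Regenerate the synthetic directional-information table.

    Value(state, residue, d) = round(base_info * max(0, 1 - |d| / span)).
    """
    rows = []
    for state in STATES:
        span = _TAPER_SPAN[state]
        for r in RESIDUES:
            base = _BASE_INFO[state][r]
            row: dict[str, object] = {"state": state, "residue": r}
            for d in OFFSETS:
                taper = max(0.0, 1.0 - abs(d) / span)
                row[f"d{d:+d}"] = int(round(base * taper))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GorModel:
    """Directional information tables plus per-state decision constants."""

    # info[state][residue] -> np.ndarray of 17 offset values (d = -8..+8)
    info: dict[str, dict[str, np.ndarray]]
    decision_constants: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in STATES}
    )

    def __post_init__(self) -> None:
        for state in STATES:
            if state not in self.info:
                raise GorError(f"table incomplete: missing state {state!r}")
            for r in RESIDUES:
                if r not in self.info[state]:
                    raise GorError(
                        f"table incomplete: missing residue {r!r} for {state!r}"
                    )
                if len(self.info[state][r]) != len(OFFSETS):
                    raise GorError(
                        f"table malformed: {state}/{r} has "
                        f"{len(self.info[state][r])} offsets, expected 17"
                    )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, decision_constants: dict[str, float] | None = None
    ) -> "GorModel":
        cols = [f"d{d:+d}" for d in OFFSETS]
        info: dict[str, dict[str, np.ndarray]] = {}
        for _, row in df.iterrows():
            info.setdefault(row["state"], {})[row["residue"]] = np.array(
                [float(row[c]) for c in cols]
            )
        return cls(info, decision_constants or {s: 0.0 for s in STATES})

    @classmethod
    def load(
        cls,
        path: str | Path | None = None,
        decision_constants: dict[str, float] | None = None,
    ) -> "GorModel":
        """Load the bundled synthetic table (or a user table of the same
        shape)."""
        if path is None:
            res = resources.files("spidrokit") / "data" / "gor_tables_synthetic.tsv"
            with resources.as_file(res) as p:
                df = pd.read_csv(p, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df, decision_constants)


@dataclass
class GorPrediction:
    sequence_id: str
    states: str  # one of "HETC" per residue
    flagged_unknown: int = 0  # residues outside the 20-letter alphabet

    def __len__(self) -> int:
        return len(self.states)


_STATE_CODE = {"helix": "H", "sheet": "E", "turn": "T", "coil": "C"}


def predict(seq: str, model: GorModel, sequence_id: str = "seq") -> GorPrediction:
    """Per-residue GOR state calls for ``seq``.

    Out-of-alphabet residues (e.g. X) contribute zero information at every
    offset and are counted in ``flagged_unknown`` (they still receive a
    call from their context). Sequences shorter than the window are scored
    over in-bounds offsets only.
    """
    if not seq:
        raise GorError("empty sequence")
    n = len(seq)
    res_idx = np.array([RESIDUES.index(c) if c in _RESIDUE_SET else -1 for c in seq])
    unknown = int(np.sum(res_idx < 0))
    # scores[s, i] = sum_d info[s][seq[i+d]][d] over in-bounds i + d
    scores = np.zeros((len(STATES), n))
    for si, state in enumerate(STATES):
        # table[residue_index, offset_index]; extra zero row for unknowns
        table = np.vstack(
            [model.info[state][r] for r in RESIDUES] + [np.zeros(len(OFFSETS))]
        )
        contrib = table[res_idx]  # (n, 17): residue j's values per offset
        for di, d in enumerate(OFFSETS):
            # residue at i + d contributes contrib[i + d, di] to position i
            lo, hi = max(0, -d), min(n, n - d)
            if lo >= hi:
                continue
            scores[si, lo:hi] += contrib[lo + d : hi + d, di]
        scores[si] -= model.decision_constants.get(state, 0.0)
    calls = np.argmax(scores, axis=0)  # first max wins: helix > sheet > turn > coil
    states = "".join(_STATE_CODE[STATES[c]] for c in calls)
    return GorPrediction(sequence_id, states, unknown)


_RESIDUE_SET = frozenset(RESIDUES)


def state_fractions(pred: GorPrediction) -> dict[str, float]:
    """Percent of residues called per state; sums to 100."""
    if not pred.states:
        raise GorError("empty prediction")
    n = len(pred.states)
    return {
        state: 100.0 * pred.states.count(code) / n
        for state, code in _STATE_CODE.items()
    }


def turn_percent(seq: str, model: GorModel | None = None) -> float:
    """Convenience: percent of residues predicted as beta-turn."""
    model = model or GorModel.load()
    return state_fractions(predict(seq, model))["turn"]
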