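"""Nearest-neighbor duplex thermodynamics for gapless probe/fragment alignments.

Duplex stability is additive over dinucleotide (nearest-neighbor, NN) steps:

    dG = sum(step dH) - T * sum(step dS) + initiation terms + salt correction

with the equilibrium constant K_eq = exp(-dG / RT).  Steps are written
``XY/WZ`` meaning 5'-XY-3' on the top (probe) strand over 3'-WZ-5' on the
bottom (target) strand; the strand-swapped presentation ``ZW/YX`` denotes the
same physical stack and resolves to the same table entry.

Probe sequences may carry abasic marks (``_``): a position whose backbone is
present but whose base is lost after synthesis.  An abasic position cannot
pair; the duplex is treated as two sub-helices joined at a nick, each run of
two or more consecutively paired bases contributing its own stacking steps and
initiation terms, while an isolated single pair contributes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import numpy as np

__all__ = [
    "R_GAS",
    "ABASIC",
    "NNParameterSet",
    "DuplexAlignment",
    "ParameterTableError",
    "InvalidAlignmentError",
    "delta_g",
    "keq",
    "load_nn_params",
    "revcomp",
]

#: Gas constant, J/(mol*K).
R_GAS = 8.314462618

#: Character marking an abasic probe position.
ABASIC = "_"

#: dG exponent clamp for K_eq; exp(+-_EXP_CLAMP) stays finite in float64.
_EXP_CLAMP = 700.0

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# integer encoding: A,C,G,T = 0..3, abasic = 4
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE[ABASIC] = 4


class ParameterTableError(KeyError):
    """A required NN table entry is absent or the table file is malformed."""


class InvalidAlignmentError(ValueError):
    """An alignment violates the duplex-geometry invariants."""


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T sequence."""
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence (A,C,G,T,_) as int8 codes 0..4."""
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-ACGT character {exc} in sequence {seq!r}") from None


def _flip(step: str) -> str:
    """Strand-swapped presentation of an XY/WZ step (-> ZW/YX)."""
    top, bottom = step.split("/")
    return bottom[::-1] + "/" + top[::-1]


@dataclass(frozen=True)
class NNArrays:
    """Dense lookup arrays for vectorized scoring.

    ``step_h[x1, x2, w, z]`` is the dH of step x1x2/wz (top bases may be the
    abasic code 4, in which case the step contributes zero).  ``missing`` marks
    contexts the loaded table cannot score (a single-mismatch step absent from
    the table -- an explicit error when encountered); ``unparameterized`` marks
    adjacent-double-mismatch contexts that are defined to contribute (0, 0)
    and are only counted for diagnostics.
    """

    step_h: np.ndarray
    step_s: np.ndarray
    missing: np.ndarray
    unparameterized: np.ndarray
    init_h: np.ndarray  # indexed (probe base code, target base code); abasic row 0
    init_s: np.ndarray
    salt_coeff: float


@dataclass
class NNParameterSet:
    """dH/dS tables for match, mismatch and initiation NN terms.

    Units: dH in J/mol, dS in J/(K*mol).  ``salt_coeff`` is the dG gained per
    phosphate pair (= per NN step) per ln[Na+], in J/mol; at the 1 M default
    the correction vanishes.
    """

    match_steps: dict[str, tuple[float, float]]
    mismatch_steps: dict[str, tuple[float, float]]
    initiation: dict[str, tuple[float, float]]  # keys "GC", "AT"
    salt_coeff: float = -476.976
    _arrays: NNArrays | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = self._missing_match_steps()
        if missing:
            raise ParameterTableError(
                f"incomplete Watson-Crick NN set; unresolvable step(s): {sorted(missing)}"
            )
        for key in ("GC", "AT"):
            if key not in self.initiation:
                raise ParameterTableError(f"missing initiation entry {key!r}")

    def _missing_match_steps(self) -> set[str]:
        out = set()
        for x1 in _BASES:
            for x2 in _BASES:
                step = f"{x1}{x2}/{_COMP[x1]}{_COMP[x2]}"
                if step not in self.match_steps and _flip(step) not in self.match_steps:
                    out.add(step)
        return out

    def step(self, step: str) -> tuple[float, float]:
        """(dH, dS) for an XY/WZ step, resolving strand symmetry.

        Raises :class:`ParameterTableError` for a context the table does not
        cover (never silently zero).
        """
        for key in (step, _flip(step)):
            if key in self.match_steps:
                return self.match_steps[key]
            if key in self.mismatch_steps:
                return self.mismatch_steps[key]
        raise ParameterTableError(f"no NN table entry for step {step}")

    def has_step(self, step: str) -> bool:
        return (
            step in self.match_steps
            or step in self.mismatch_steps
            or _flip(step) in self.match_steps
            or _flip(step) in self.mismatch_steps
        )

    def initiation_for(
        self, probe_base: str, target_base: str | None = None
    ) -> tuple[float, float]:
        """Initiation/termination term for a terminal pair.

        GC-class if either base of the pair is G or C, else AT-class; for a
        Watson-Crick terminal pair this is the standard rule, and keying on
        the pair rather than one strand keeps duplex energies exactly
        invariant under swapping the strand presentation.
        """
        gc = probe_base in "GC" or (target_base is not None and target_base in "GC")
        return self.initiation["GC" if gc else "AT"]

    def scaled(self, step: str, ratio: float) -> "NNParameterSet":
        """Copy of the set with one step's dH multiplied by ``ratio``."""
        match = dict(self.match_steps)
        mism = dict(self.mismatch_steps)
        for key in (step, _flip(step)):
            if key in match:
                h, s = match[key]
                match[key] = (h * ratio, s)
                break
            if key in mism:
                h, s = mism[key]
                mism[key] = (h * ratio, s)
                break
        else:
            raise ParameterTableError(f"unknown step id {step!r}")
        return NNParameterSet(match, mism, dict(self.initiation), self.salt_coeff)

    def as_arrays(self) -> NNArrays:
        """Dense (cached) lookup arrays for the vectorized scorer."""
        if self._arrays is not None:
            return self._arrays
        step_h = np.zeros((5, 5, 4, 4))
        step_s = np.zeros((5, 5, 4, 4))
        missing = np.zeros((5, 5, 4, 4), dtype=bool)
        unparam = np.zeros((5, 5, 4, 4), dtype=bool)
        for x1 in range(4):
            for x2 in range(4):
                for w in range(4):
                    for z in range(4):
                        key = (
                            f"{_BASES[x1]}{_BASES[x2]}/{_BASES[w]}{_BASES[z]}"
                        )
                        n_mm = (_COMP[_BASES[x1]] != _BASES[w]) + (
                            _COMP[_BASES[x2]] != _BASES[z]
                        )
                        if self.has_step(key):
                            h, s = self.step(key)
                            step_h[x1, x2, w, z] = h
                            step_s[x1, x2, w, z] = s
                        elif n_mm == 2:
                            unparam[x1, x2, w, z] = True  # contributes (0, 0)
                        else:
                            missing[x1, x2, w, z] = True
        init_h = np.zeros((5, 4))
        init_s = np.zeros((5, 4))
        for b in range(4):
            for t in range(4):
                h, s = self.initiation_for(_BASES[b], _BASES[t])
                init_h[b, t], init_s[b, t] = h, s
        arrays = NNArrays(step_h, step_s, missing, unparam, init_h, init_s, self.salt_coeff)
        self._arrays = arrays
        return arrays


@dataclass
class DuplexAlignment:
    """A gapless alignment of a target fragment against a probe.

    ``probe_seq`` is written 5'->3' and may carry abasic marks; ``fragment_seq``
    is the bound target fragment written 5'->3'.  The duplex is antiparallel:
    the fragment's first (5') base sits at probe position ``offset_k``
    (1-based) and successive fragment bases pair with *decreasing* probe
    positions.  Fragment bases falling outside the probe are unpaired
    overhangs and contribute no energy.
    """

    probe_seq: str
    fragment_seq: str
    offset_k: int

    def __post_init__(self) -> None:
        if len(self.probe_seq) < 2:
            raise InvalidAlignmentError("probe shorter than 2 bases")
        if any(c not in _CODE for c in self.probe_seq):
            raise InvalidAlignmentError(f"bad probe sequence {self.probe_seq!r}")
        if any(c not in _BASES for c in self.fragment_seq):
            raise InvalidAlignmentError(f"bad fragment sequence {self.fragment_seq!r}")
        if len(self.paired_positions()) < 2:
            raise InvalidAlignmentError(
                "alignment must pair at least 2 non-abasic probe positions"
            )

    def paired_positions(self) -> list[tuple[int, int]]:
        """(probe_pos_1based, fragment_index_0based) for in-probe, non-abasic pairs."""
        out = []
        for f_idx in range(len(self.fragment_seq)):
            pos = self.offset_k - f_idx
            if 1 <= pos <= len(self.probe_seq) and self.probe_seq[pos - 1] != ABASIC:
                out.append((pos, f_idx))
        return out

    def pair_states(self) -> list[str]:
        """Per in-probe position (ascending): 'match', 'mismatch' or 'abasic'."""
        states = []
        for f_idx in range(len(self.fragment_seq) - 1, -1, -1):
            pos = self.offset_k - f_idx
            if not 1 <= pos <= len(self.probe_seq):
                continue
            p = self.probe_seq[pos - 1]
            if p == ABASIC:
                states.append("abasic")
            elif _COMP[p] == self.fragment_seq[f_idx]:
                states.append("match")
            else:
                states.append("mismatch")
        return states


def _aligned_runs(aln: DuplexAlignment) -> Iterator[list[tuple[str, str]]]:
    """Maximal runs of consecutive paired (non-abasic) positions.

    Yields runs as lists of (probe_base, target_base) ordered 5'->3' along the
    probe; consecutive means adjacent in *probe* coordinates, so an abasic
    position or the probe end terminates a run.
    """
    pairs = {}  # probe position -> target base
    for pos, f_idx in aln.paired_positions():
        pairs[pos] = aln.fragment_seq[f_idx]
    run: list[tuple[str, str]] = []
    for pos in range(1, len(aln.probe_seq) + 1):
        if pos in pairs:
            run.append((aln.probe_seq[pos - 1], pairs[pos]))
        elif run:
            yield run
            run = []
    if run:
        yield run


def delta_g(
    aln: DuplexAlignment,
    params: NNParameterSet,
    temp: float,
    na: float = 1.0,
    diagnostics: dict | None = None,
) -> float:
    """Free energy (J/mol) of a duplex alignment at temperature ``temp`` (K).

    Scalar reference implementation: accumulates NN steps position by
    position, adds initiation terms per sub-helix run and the [Na+]
    correction.  ``diagnostics`` (optional dict) receives a count of
    adjacent-double-mismatch steps that carry no table value and were scored
    as (0, 0) under key ``"unparameterized_steps"``.
    """
    if temp <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if na <= 0:
        raise ValueError("[Na+] must be positive (molar)")
    dh = ds = 0.0
    n_steps = 0
    for run in _aligned_runs(aln):
        if len(run) < 2:
            continue  # an isolated pair has no stack and no stable helix
        for (p1, t1), (p2, t2) in zip(run, run[1:]):
            n_steps += 1  # salt correction counts every backbone step
            step = f"{p1}{p2}/{t1}{t2}"
            n_mm = (_COMP[p1] != t1) + (_COMP[p2] != t2)
            if n_mm == 2 and not params.has_step(step):
                if diagnostics is not None:
                    diagnostics["unparameterized_steps"] = (
                        diagnostics.get("unparameterized_steps", 0) + 1
                    )
                continue
            h, s = params.step(step)
            dh += h
            ds += s
        for terminal_probe, terminal_target in (run[0], run[-1]):
            h, s = params.initiation_for(terminal_probe, terminal_target)
            dh += h
            ds += s
    return dh - temp * ds + params.salt_coeff * n_steps * np.log(na)


def keq(dg: float, temp: float) -> float:
    """Equilibrium constant exp(-dG / RT); strictly decreasing in dG.

    Extreme dG values are clamped so the result stays finite; a clamp is
    reported through :mod:`warnings`.
    """
    if temp <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    x = -np.asarray(dg, dtype=float) / (R_GAS * temp)
    if np.any(np.abs(x) > _EXP_CLAMP):
        warnings.warn(
            "dG magnitude exceeds the finite K_eq range; exponent clamped to +-700",
            RuntimeWarning,
            stacklevel=2,
        )
        x = np.clip(x, -_EXP_CLAMP, _EXP_CLAMP)
    return float(np.exp(x)) if np.ndim(dg) == 0 else np.exp(x)


def _parse_nn_rows(path) -> Iterator[tuple[int, str, float, float, str]]:
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = ["step", "dH", "dS", "class"]
                if header[: len(required)] != required:
                    raise ParameterTableError(
                        f"{path}: line {lineno}: expected columns {required}, got {header}"
                    )
                continue
            if len(fields) < 4:
                raise ParameterTableError(
                    f"{path}: line {lineno}: malformed row {line!r}"
                )
            step, dh, ds, cls = fields[:4]
            try:
                yield lineno, step, float(dh), float(ds), cls
            except ValueError:
                raise ParameterTableError(
                    f"{path}: line {lineno}: non-numeric dH/dS in {line!r}"
                ) from None


def default_nn_path():
    """Path to the bundled unified NN parameter table."""
    return resources.files("probeforest") / "data" / "nn_unified.tsv"


def load_nn_params(path=None, override=None, salt_coeff: float = -476.976) -> NNParameterSet:
    """Load an NN parameter set from a TSV (step, dH, dS, class).

    With no ``path`` the bundled unified literature table is used.  An
    ``override`` file may replace individual entries (e.g. a refit mismatch
    table); overridden steps replace the base values, all others are kept.
    """
    if path is None:
        path = default_nn_path()
    match: dict[str, tuple[float, float]] = {}
    mism: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    seen: set[str] = set()
    for lineno, step, dh, ds, cls in _parse_nn_rows(path):
        if step in seen:
            raise ParameterTableError(f"{path}: line {lineno}: duplicate step {step}")
        seen.add(step)
        if cls == "match":
            match[step] = (dh, ds)
        elif cls == "mismatch":
            mism[step] = (dh, ds)
        elif cls == "initiation":
            init[step.removeprefix("init_")] = (dh, ds)
        else:
            raise ParameterTableError(
                f"{path}: line {lineno}: unknown class {cls!r} for step {step}"
            )
    params = NNParameterSet(match, mism, init, salt_coeff)
    if override is not None:
        for lineno, step, dh, ds, cls in _parse_nn_rows(override):
            if cls == "match":
                match[_canonical(step, match)] = (dh, ds)
            elif cls == "mismatch":
                mism[_canonical(step, mism)] = (dh, ds)
            elif cls == "initiation":
                init[step.removeprefix("init_")] = (dh, ds)
            else:
                raise ParameterTableError(
                    f"{override}: line {lineno}: unknown class {cls!r}"
                )
        params = NNParameterSet(match, mism, init, salt_coeff)
    return params


def _canonical(step: str, table: dict) -> str:
    """Key under which ``step`` already lives in ``table`` (else ``step``)."""
    if step in table:
        return step
    flipped = _flip(step)
    return flipped if flipped in table else step
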