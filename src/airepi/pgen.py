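"""A small, fully enumerable V(D)J generative model.

A rearrangement is built as: pick a V segment (keeping its 3' suffix),
delete ``v_trim`` bases from its end, insert a random nucleotide string
(length and bases drawn independently), delete ``j_trim`` bases from the
start of a J segment prefix, and concatenate. The generation probability
of a nucleotide sequence is the exact sum over every event tuple whose
concatenation equals it — no Monte Carlo. The model deliberately omits
D segments and positional insertion context; it serves threshold
classification (public vs private) and repertoire means, not
per-sequence agreement with full IGoR-parameterized models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .io import Repertoire

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_SUM_TOL = 1e-9


def _check_probs(vec, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1 or vec.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D probability vector")
    if np.any(vec < 0):
        raise ValidationError(f"{name} has negative entries")
    if abs(vec.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"{name} sums to {vec.sum()!r}, not 1")
    return vec


@dataclass
class GenerativeModel:
    """Parameters of the toy recombination process.

    ``v_segments`` / ``j_segments`` are ``(name, sequence, probability)``
    triples holding the V 3' suffix and J 5' prefix that survive into the
    junction. Trim distributions are indexed by trim length (index 0 =
    no trimming); trims longer than a segment leave an empty remnant.
    """

    v_segments: list[tuple[str, str, float]]
    j_segments: list[tuple[str, str, float]]
    insertion_length_probs: np.ndarray
    insertion_base_probs: np.ndarray
    v_trim_probs: np.ndarray
    j_trim_probs: np.ndarray

    def __post_init__(self):
        for side, segs in (("v", self.v_segments), ("j", self.j_segments)):
            if not segs:
                raise ValidationError(f"{side}_segments must be non-empty")
            for name, seq, _ in segs:
                if not seq or any(b not in _BASE_INDEX for b in seq):
                    raise ValidationError(
                        f"segment {name!r} has invalid sequence {seq!r}"
                    )
            _check_probs([p for _, _, p in segs], f"{side}_segment probabilities")
        self.insertion_length_probs = _check_probs(
            self.insertion_length_probs, "insertion_length_probs"
        )
        self.insertion_base_probs = _check_probs(
            self.insertion_base_probs, "insertion_base_probs"
        )
        if self.insertion_base_probs.size != 4:
            raise ValidationError("insertion_base_probs must have 4 entries (A,C,G,T)")
        self.v_trim_probs = _check_probs(self.v_trim_probs, "v_trim_probs")
        self.j_trim_probs = _check_probs(self.j_trim_probs, "j_trim_probs")

    @property
    def max_insertion(self) -> int:
        return self.insertion_length_probs.size - 1


def _remnants(segments, trim_probs, v_side: bool):
    """Yield (name, remnant string, probability) for every segment x trim."""
    for name, seq, p_seg in segments:
        for trim, p_trim in enumerate(trim_probs):
            if p_trim == 0.0:
                continue
            cut = min(trim, len(seq))
            remnant = seq[: len(seq) - cut] if v_side else seq[cut:]
            yield name, trim, remnant, p_seg * p_trim


def pgen_nt(seq: str, model: GenerativeModel) -> float:
    """Exact generation probability of a nucleotide sequence.

    Marginalizes over every (V, v_trim, insertion, j_trim, J) tuple whose
    concatenation equals ``seq``; the insertion string between a matching
    V remnant prefix and J remnant suffix is unique, so its probability
    is a closed-form product over bases.
    """
    seq = seq.upper()
    if any(b not in _BASE_INDEX for b in seq):
        raise ValidationError(f"sequence contains non-ACGT characters: {seq!r}")

    n = len(seq)
    total = 0.0
    j_options = list(_remnants(model.j_segments, model.j_trim_probs, v_side=False))
    for _, _, v_rem, p_v in _remnants(model.v_segments, model.v_trim_probs, v_side=True):
        lv = len(v_rem)
        if lv > n or not seq.startswith(v_rem):
            continue
        for _, _, j_rem, p_j in j_options:
            lj = len(j_rem)
            mid_len = n - lv - lj
            if mid_len < 0 or mid_len > model.max_insertion:
                continue
            if lj and not seq.endswith(j_rem):
                continue
            p_mid = model.insertion_length_probs[mid_len]
            if p_mid == 0.0:
                continue
            for b in seq[lv : lv + mid_len]:
                p_mid *= model.insertion_base_probs[_BASE_INDEX[b]]
            total += p_v * p_mid * p_j
    return float(total)


def sample_rearrangement(model: GenerativeModel, seed) -> tuple[str, tuple]:
    """Draw one rearrangement; returns ``(sequence, event tuple)``.

    ``seed`` may be an integer or a ``numpy.random.Generator``. The event
    tuple is ``(v_name, v_trim, insertion, j_trim, j_name)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    v_probs = [p for _, _, p in model.v_segments]
    j_probs = [p for _, _, p in model.j_segments]
    vi = rng.choice(len(model.v_segments), p=v_probs)
    ji = rng.choice(len(model.j_segments), p=j_probs)
    v_trim = int(rng.choice(model.v_trim_probs.size, p=model.v_trim_probs))
    j_trim = int(rng.choice(model.j_trim_probs.size, p=model.j_trim_probs))
    ins_len = int(
        rng.choice(model.insertion_length_probs.size, p=model.insertion_length_probs)
    )
    insertion = "".join(
        _BASES[rng.choice(4, p=model.insertion_base_probs)] for _ in range(ins_len)
    )

    v_name, v_seq, _ = model.v_segments[vi]
    j_name, j_seq, _ = model.j_segments[ji]
    v_rem = v_seq[: len(v_seq) - min(v_trim, len(v_seq))]
    j_rem = j_seq[min(j_trim, len(j_seq)) :]
    seq = v_rem + insertion + j_rem
    return seq, (v_name, v_trim, insertion, j_trim, j_name)


def annotate_pgen(rep: Repertoire, model: GenerativeModel) -> Repertoire:
    """Return a copy of ``rep`` with every clonotype's pgen field filled."""
    clonotypes = {}
    n_zero = 0
    for key, clone in rep.clonotypes.items():
        p = pgen_nt(clone.cdr3_nt, model)
        if p == 0.0:
            n_zero += 1
        clonotypes[key] = dc_replace(clone, pgen=p)
    if n_zero:
        logger.warning(
            "%s: %d clonotype(s) unreachable under the generative model (pgen 0)",
            rep.subject_id,
            n_zero,
        )
    return Repertoire(
        subject_id=rep.subject_id,
        locus=rep.locus,
        clonotypes=clonotypes,
        normalized_to=rep.normalized_to,
        seed=rep.seed,
    )


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: GenerativeModel) -> dict:
    return {
        "v_segments": [[n, s, float(p)] for n, s, p in model.v_segments],
        "j_segments": [[n, s, float(p)] for n, s, p in model.j_segments],
        "insertion_length_probs": [float(x) for x in model.insertion_length_probs],
        "insertion_base_probs": [float(x) for x in model.insertion_base_probs],
        "v_trim_probs": [float(x) for x in model.v_trim_probs],
        "j_trim_probs": [float(x) for x in model.j_trim_probs],
    }


def model_from_dict(d: dict) -> GenerativeModel:
    return GenerativeModel(
        v_segments=[(n, s, float(p)) for n, s, p in d["v_segments"]],
        j_segments=[(n, s, float(p)) for n, s, p in d["j_segments"]],
        insertion_length_probs=np.asarray(d["insertion_length_probs"], dtype=float),
        insertion_base_probs=np.asarray(d["insertion_base_probs"], dtype=float),
        v_trim_probs=np.asarray(d["v_trim_probs"], dtype=float),
        j_trim_probs=np.asarray(d["j_trim_probs"], dtype=float),
    )


def save_model(model: GenerativeModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=True))


def load_model(path: str | Path) -> GenerativeModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))
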