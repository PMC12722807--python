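"""Symbolic character encoding of transcripts.

Each character of a cleaned transcript is mapped to a small positive integer
(``a``..``z`` -> 1..26, space -> 27, ``.`` -> 28, a fixed extension for the
remaining printable characters), turning text into a symbolic time series
whose repetition structure can be analyzed with recurrence plots.  The
mapping is pure indexing — downstream recurrence uses symbol *equality*, so
the numeric values carry no metric meaning.  Sequences are standardized to a
common length by end-padding with the reserved code 0 and end-truncation, so
the information-rich openings of transcripts are preserved.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

PAD_CODE = 0

#: Default sequence length for batch standardization. Most picture-description
#: transcripts fit within 512 characters without truncation while keeping
#: recurrence matrices tractable.
DEFAULT_TARGET_LENGTH = 512


@dataclass(frozen=True)
class AlphabetMap:
    """Injective character -> positive-integer mapping with a pad and unknown code."""

    mapping: dict[str, int]
    unknown_code: int
    pad_code: int = PAD_CODE

    def __post_init__(self):
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise ValueError("alphabet mapping must be injective")
        if self.pad_code in codes or self.unknown_code in codes:
            raise ValueError("pad/unknown codes must not be assigned to characters")

    def code(self, char: str) -> int:
        return self.mapping.get(char, self.unknown_code)

    @property
    def inverse(self) -> dict[int, str]:
        return {v: k for k, v in self.mapping.items()}

    def fingerprint(self) -> str:
        import hashlib

        payload = json.dumps(sorted(self.mapping.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_alphabet() -> AlphabetMap:
    """The fixed default alphabet.

    ``a``..``z`` -> 1..26, space -> 27, ``.`` -> 28, comma -> 29,
    apostrophe -> 30, ``?`` -> 31, hyphen -> 32, digits ``0``..``9`` -> 33..42;
    any other character maps to the unknown code 43.
    """
    mapping = {chr(ord("a") + i): i + 1 for i in range(26)}
    mapping[" "] = 27
    mapping["."] = 28
    mapping[","] = 29
    mapping["'"] = 30
    mapping["?"] = 31
    mapping["-"] = 32
    for d in range(10):
        mapping[str(d)] = 33 + d
    return AlphabetMap(mapping=mapping, unknown_code=43)


@dataclass
class SymbolSequence:
    """Integer-coded character sequence; pad codes only as a contiguous suffix."""

    codes: np.ndarray
    effective_length: int
    transcript_id: str = ""

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if np.any(self.codes[: self.effective_length] == PAD_CODE):
            raise ValueError("pad code inside the effective prefix")
        if np.any(self.codes[self.effective_length :] != PAD_CODE):
            raise ValueError("non-pad code inside the pad suffix")

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    @property
    def active(self) -> np.ndarray:
        """The non-pad prefix."""
        return self.codes[: self.effective_length]


def normalize_text(text: str, lowercase: bool = True) -> str:
    """Unicode NFC normalization and (by default) lowercase folding."""
    text = unicodedata.normalize("NFC", text)
    return text.lower() if lowercase else text


def encode_text(
    text: str,
    alphabet: AlphabetMap | None = None,
    transcript_id: str = "",
    lowercase: bool = True,
) -> SymbolSequence:
    """Map text to a symbol sequence, one code per normalized character."""
    if alphabet is None:
        alphabet = default_alphabet()
    normalized = normalize_text(text, lowercase=lowercase)
    if not normalized:
        raise ValueError("nothing to encode: empty text")
    codes = np.fromiter(
        (alphabet.code(c) for c in normalized), dtype=np.int64, count=len(normalized)
    )
    return SymbolSequence(codes=codes, effective_length=len(codes), transcript_id=transcript_id)


def standardize_length(seq: SymbolSequence, target_length: int) -> SymbolSequence:
    """Pad with trailing zeros or truncate at the end to `target_length`."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    n = len(seq)
    if n >= target_length:
        codes = seq.codes[:target_length].copy()
        eff = min(seq.effective_length, target_length)
    else:
        codes = np.concatenate([seq.codes, np.zeros(target_length - n, dtype=np.int64)])
        eff = seq.effective_length
    return SymbolSequence(codes=codes, effective_length=eff, transcript_id=seq.transcript_id)


def decode(seq: SymbolSequence, alphabet: AlphabetMap | None = None) -> str:
    """Inverse mapping of the non-pad prefix; pad suffix is dropped."""
    if alphabet is None:
        alphabet = default_alphabet()
    inverse = alphabet.inverse
    chars = []
    for pos, code in enumerate(seq.active):
        code = int(code)
        if code == alphabet.unknown_code:
            chars.append("�")
        elif code in inverse:
            chars.append(inverse[code])
        else:
            raise ValueError(f"code {code} at position {pos} is outside the alphabet")
    return "".join(chars)


def save_sequences(seqs: list[SymbolSequence], path: str | Path, alphabet: AlphabetMap,
                   target_length: int) -> None:
    """Write sequences as a compressed array plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        codes=np.stack([s.codes for s in seqs]),
        effective_lengths=np.array([s.effective_length for s in seqs]),
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "alphabet_fingerprint": alphabet.fingerprint(),
                "target_length": target_length,
                "transcript_ids": [s.transcript_id for s in seqs],
            },
            indent=2,
        )
    )


class SymbolEncoder(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: list of texts -> (n, target_length) code matrix.

    Parameters
    ----------
    target_length : int
        Common sequence length after end-padding/truncation.
    lowercase : bool
        Fold case before encoding.
    """

    def __init__(self, target_length: int = DEFAULT_TARGET_LENGTH, lowercase: bool = True):
        self.target_length = target_length
        self.lowercase = lowercase

    def fit(self, X, y=None):
        self.alphabet_ = default_alphabet()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "alphabet_"):
            self.fit(X)
        rows = []
        for text in X:
            seq = standardize_length(
                encode_text(text, self.alphabet_, lowercase=self.lowercase),
                self.target_length,
            )
            rows.append(seq.codes)
        return np.stack(rows)
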