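"""Reading CHAT-format speech transcripts.

Transcripts from picture-description tasks (e.g. the Cookie Theft task) are
distributed in the TalkBank CHAT standard: ``@`` header lines, ``*SPEAKER:``
main tiers and ``%`` dependent tiers.  This module isolates the participant's
speech, applies a configurable markup-cleaning policy, and assembles a labeled
corpus table.  Only the participant main tier survives; interviewer
utterances, dependent tiers and analysis codes are dropped so that downstream
character-level encoding sees speech content plus the paralinguistic marks
(pauses, fillers) the cleaning policy chooses to keep.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_LABELS = ("control", "impaired")


class ChatParseError(ValueError):
    """Raised for structurally unreadable CHAT content."""


class EmptyTranscriptError(ChatParseError):
    """Raised when a file contains no participant speech."""


@dataclass(frozen=True)
class CleaningPolicy:
    """Per-utterance CHAT markup handling.

    The defaults keep paralinguistic signal: fillers survive as bare words and
    pause marks become a ``.`` so both remain visible to character-level
    encoding, while analysis codes (square brackets, retracing delimiters,
    timing bullets) are stripped.
    """

    pause_to_period: bool = True      # "(.)", "(..)", "(...)" -> "."
    keep_fillers: bool = True         # "&-uh" / "&uh" -> "uh"; False drops them
    strip_event_codes: bool = True    # "[...]" deleted
    strip_retracing: bool = True      # "<", ">" removed, words kept


DEFAULT_POLICY = CleaningPolicy()

_PAUSE_RE = re.compile(r"\(\.{1,3}\)")
_BRACKET_RE = re.compile(r"\[[^\[\]]*\]")
_BULLET_RE = re.compile("\x15[^\x15]*\x15")
_FILLER_RE = re.compile(r"(?<!\S)&[-=]?")
_WS_RE = re.compile(r"\s+")


@dataclass
class TranscriptRecord:
    """One participant transcript: cleaned participant-only text plus identity."""

    transcript_id: str
    participant_id: str
    label: str | None
    text: str
    source_path: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class CorpusTable:
    """Ordered collection of transcripts with per-class counts."""

    records: list[TranscriptRecord]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    @property
    def texts(self) -> list[str]:
        return [rec.text for rec in self.records]

    @property
    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]

    @property
    def participant_ids(self) -> list[str]:
        return [rec.participant_id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in self.records],
                "participant_id": [r.participant_id for r in self.records],
                "label": [r.label for r in self.records],
                "text": [r.text for r in self.records],
                "source_path": [r.source_path for r in self.records],
            }
        )


def clean_utterance(raw: str, policy: CleaningPolicy = DEFAULT_POLICY) -> str:
    """Apply the cleaning policy to the content of one main-tier line.

    `raw` is the text after the ``*PAR:`` prefix.  Rules, in order: timing
    bullets stripped; pause marks collapsed to ``.``; square-bracket codes
    deleted (a warning is logged and the literal text kept if brackets are
    unbalanced); angle-bracket retracing delimiters removed with the retraced
    words kept; filler prefixes ``&-``/``&=``/``&`` stripped (or the whole
    token dropped when fillers are not kept); whitespace collapsed.
    """
    text = _BULLET_RE.sub(" ", raw)
    if policy.pause_to_period:
        text = _PAUSE_RE.sub(" . ", text)
    if policy.strip_event_codes:
        if text.count("[") != text.count("]"):
            logger.warning("unbalanced brackets in utterance %r; keeping literal text", raw)
        else:
            text = _BRACKET_RE.sub(" ", text)
    if policy.strip_retracing:
        text = text.replace("<", " ").replace(">", " ")
    if policy.keep_fillers:
        text = _FILLER_RE.sub("", text)
    else:
        text = re.sub(r"(?<!\S)&\S+", " ", text)
    text = unicodedata.normalize("NFC", text)
    return _WS_RE.sub(" ", text).strip()


def _iter_main_tiers(raw_text: str) -> Iterable[tuple[str, str, int]]:
    """Yield (speaker, utterance, line_number) for each main tier.

    Continuation lines (beginning with a tab) extend the preceding tier.
    """
    current: tuple[str, str, int] | None = None
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if line.startswith("\t") and current is not None:
            current = (current[0], current[1] + " " + line.strip(), current[2])
            continue
        if current is not None:
            yield current
            current = None
        if not line or line[0] in "@%" or line.startswith("\t"):
            continue
        if line.startswith("*"):
            if ":" not in line:
                raise ChatParseError(f"malformed main tier at line {lineno}: {line!r}")
            speaker, _, content = line[1:].partition(":")
            current = (speaker.strip(), content.strip(), lineno)
        elif line.strip():
            raise ChatParseError(f"unrecognized line {lineno}: {line!r}")
    if current is not None:
        yield current


def parse_chat(
    raw_text: str,
    policy: CleaningPolicy = DEFAULT_POLICY,
    speaker: str = "PAR",
    transcript_id: str = "",
    participant_id: str = "",
    label: str | None = None,
    source_path: str = "",
) -> TranscriptRecord:
    """Parse one CHAT file's content into a participant-only transcript.

    Only main-tier utterances of `speaker` (default ``PAR``) are retained,
    cleaned per `policy` and concatenated in file order with single spaces.
    Raises :class:`EmptyTranscriptError` if no participant speech is found.
    """
    utterances = []
    for spk, content, _lineno in _iter_main_tiers(raw_text):
        if spk == speaker:
            cleaned = clean_utterance(content, policy)
            if cleaned:
                utterances.append(cleaned)
    if not utterances:
        raise EmptyTranscriptError(
            f"empty transcript: no *{speaker} speech found"
            + (f" in {source_path}" if source_path else "")
        )
    return TranscriptRecord(
        transcript_id=transcript_id,
        participant_id=participant_id,
        label=label,
        text=" ".join(utterances),
        source_path=source_path,
    )


def load_corpus(
    paths: Sequence[str | Path],
    metadata: pd.DataFrame | str | Path,
    policy: CleaningPolicy = DEFAULT_POLICY,
    speaker: str = "PAR",
) -> CorpusTable:
    """Assemble a labeled corpus from CHAT files plus a metadata table.

    `metadata` needs columns ``transcript_id``, ``participant_id``, ``label``;
    optional demographic columns (age, gender, mmse, education) are carried
    into each record's ``meta``.  The transcript id of a file is its stem.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    required = {"transcript_id", "participant_id", "label"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    meta_by_id: Mapping[str, pd.Series] = {
        str(row.transcript_id): row for row in metadata.itertuples()
    }
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        tid = path.stem
        if tid in seen:
            raise ValueError(f"duplicate transcript_id {tid!r}")
        seen.add(tid)
        if tid not in meta_by_id:
            raise ValueError(f"transcript {tid!r} has no metadata row")
        row = meta_by_id[tid]
        if row.label not in VALID_LABELS:
            raise ValueError(
                f"transcript {tid!r} has label {row.label!r}; expected one of {VALID_LABELS}"
            )
        extra = {
            k: getattr(row, k)
            for k in ("age", "gender", "mmse", "education")
            if hasattr(row, k) and pd.notna(getattr(row, k))
        }
        rec = parse_chat(
            path.read_text(),
            policy=policy,
            speaker=speaker,
            transcript_id=tid,
            participant_id=str(row.participant_id),
            label=row.label,
            source_path=str(path),
        )
        rec.meta = extra
        records.append(rec)
    return CorpusTable(records=records)
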