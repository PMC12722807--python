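"""Synthetic two-class CHAT corpora with controllable fluency contrasts.

The real corpora this pipeline targets (Cookie Theft picture descriptions)
are access-restricted, so the generator emits CHAT files whose two classes
differ in the disfluency dimensions the method is designed to detect:
filler insertion ("uh"/"um"), immediate word repetition, pause marks
"(.)" and early utterance fragmentation, plus utterance length.  Both
classes share one scene vocabulary, so separation comes from temporal/
fluency structure rather than lexical content (a per-profile vocabulary
override exists for constructing keyword-separable corpora).

The generator writes genuine CHAT markup (``@Begin``/``@End`` headers,
``*INV``/``*PAR`` tiers, ``&-uh`` fillers, ``(.)`` pauses) so the cleaning
policy in :mod:`symrec.chat_io` is genuinely exercised; ``chat_markup=False``
emits the same content as plain tokens for unit tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Cookie-Theft scene vocabulary (nouns/verbs of the standard picture).
DEFAULT_VOCABULARY = (
    "boy", "girl", "mother", "cookie", "jar", "stool", "sink", "water",
    "plate", "reach", "fall", "wash", "overflow", "take", "dry",
)

_PROMPTS = (
    "tell me everything you see going on in this picture .",
    "what else do you see ?",
    "anything more ?",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Per-word disfluency rates and utterance geometry of one speaker class."""

    filler_rate: float = 0.0
    repetition_rate: float = 0.0
    pause_rate: float = 0.0
    fragment_rate: float = 0.0
    utterance_count: tuple[int, int] = (8, 14)
    words_per_utterance: tuple[int, int] = (8, 15)
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self):
        for name in ("filler_rate", "repetition_rate", "pause_rate", "fragment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("utterance_count", "words_per_utterance"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range {name}={getattr(self, name)}")
        if len(self.vocabulary) < 10:
            raise ValueError("vocabulary must have at least 10 words")


@dataclass(frozen=True)
class ClassProfile:
    """A label plus its generator parameters."""

    label: str
    params: GeneratorParams


def default_profiles() -> tuple[ClassProfile, ClassProfile]:
    """Default control/impaired contrast.

    The impaired profile has strictly higher filler, repetition, pause and
    fragmentation rates and shorter utterances — a detectable but not trivial
    contrast calibrated once as the package's study condition.
    """
    control = ClassProfile(
        "control",
        GeneratorParams(filler_rate=0.02, repetition_rate=0.01, pause_rate=0.05,
                        fragment_rate=0.05, words_per_utterance=(8, 15)),
    )
    impaired = ClassProfile(
        "impaired",
        GeneratorParams(filler_rate=0.15, repetition_rate=0.10, pause_rate=0.20,
                        fragment_rate=0.25, words_per_utterance=(3, 8)),
    )
    return control, impaired


def _check_ordering(control: ClassProfile, impaired: ClassProfile) -> None:
    c, i = control.params, impaired.params
    ok = (
        i.filler_rate > c.filler_rate
        and i.repetition_rate > c.repetition_rate
        and i.pause_rate > c.pause_rate
        and i.fragment_rate > c.fragment_rate
        and i.words_per_utterance[1] <= c.words_per_utterance[1]
    )
    if not ok:
        raise ValueError("impaired profile must have strictly higher disfluency rates "
                         "and no longer utterances than the control profile")


def _participant_utterance(params: GeneratorParams, rng: np.random.Generator,
                           chat_markup: bool) -> str:
    n_words = int(rng.integers(params.words_per_utterance[0],
                               params.words_per_utterance[1] + 1))
    if params.fragment_rate and rng.random() < params.fragment_rate:
        n_words = max(1, int(rng.integers(1, n_words + 1)))
    tokens: list[str] = []
    vocab = params.vocabulary
    prev = None
    for _ in range(n_words):
        if params.filler_rate and rng.random() < params.filler_rate:
            filler = "uh" if rng.random() < 0.5 else "um"
            tokens.append(f"&-{filler}" if chat_markup else filler)
        # avoid accidental immediate repeats: doubling comes only from the
        # repetition mechanism
        word = vocab[int(rng.integers(len(vocab)))]
        while word == prev:
            word = vocab[int(rng.integers(len(vocab)))]
        prev = word
        tokens.append(word)
        if params.repetition_rate and rng.random() < params.repetition_rate:
            tokens.append(word)
        if params.pause_rate and rng.random() < params.pause_rate:
            tokens.append("(.)" if chat_markup else ".")
    tokens.append(".")
    return " ".join(tokens)


def sample_transcript(profile: ClassProfile, rng: np.random.Generator,
                      chat_markup: bool = True) -> str:
    """One syntactically valid CHAT file: headers plus alternating INV/PAR tiers."""
    params = profile.params
    n_utts = int(rng.integers(params.utterance_count[0], params.utterance_count[1] + 1))
    lines = [
        "@Begin",
        "@Languages:\teng",
        "@Participants:\tPAR Participant, INV Investigator",
        "@ID:\teng|synthetic|PAR|||||Participant|||",
        "@ID:\teng|synthetic|INV|||||Investigator|||",
    ]
    for u in range(n_utts):
        if u == 0 or rng.random() < 0.2:
            lines.append(f"*INV:\t{_PROMPTS[int(rng.integers(len(_PROMPTS)))]}")
        lines.append(f"*PAR:\t{_participant_utterance(params, rng, chat_markup)}")
    lines.append("@End")
    return "\n".join(lines) + "\n"


def generate_corpus(
    n_control: int,
    n_impaired: int,
    outdir: str | Path,
    profiles: tuple[ClassProfile, ClassProfile] | None = None,
    n_participants_per_class: int | None = None,
    seed: int = 0,
    chat_markup: bool = True,
) -> tuple[list[Path], Path]:
    """Write a two-class corpus of .cha files plus metadata.csv and a manifest.

    Transcripts are spread over ``n_participants_per_class`` participants per
    class (default 2/3 of the transcript count, so some participants
    contribute several transcripts and the grouping logic is exercised).
    Returns (list of transcript paths, metadata path).  Byte-identical under
    a fixed seed.
    """
    if n_control < 1 or n_impaired < 1:
        raise ValueError("need at least one transcript per class")
    if profiles is None:
        profiles = default_profiles()
    control, impaired = profiles
    _check_ordering(control, impaired)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows = []
    paths: list[Path] = []
    for profile, n_files, prefix in ((control, n_control, "c"), (impaired, n_impaired, "d")):
        n_parts = n_participants_per_class or max(1, (2 * n_files) // 3)
        if n_parts > n_files:
            raise ValueError("more participants than transcripts in a class")
        for i in range(n_files):
            pid = f"{prefix}{(i % n_parts) + 1:03d}"
            tid = f"{prefix}{i + 1:03d}-t{i // n_parts + 1}"
            path = outdir / f"{tid}.cha"
            path.write_text(sample_transcript(profile, rng, chat_markup=chat_markup))
            paths.append(path)
            rows.append(
                {"transcript_id": tid, "participant_id": pid, "label": profile.label,
                 "age": "", "gender": "", "mmse": ""}
            )
    meta_path = outdir / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    manifest = {
        "seed": seed,
        "n_control": n_control,
        "n_impaired": n_impaired,
        "chat_markup": chat_markup,
        "profiles": {
            p.label: dataclasses.asdict(p.params) for p in (control, impaired)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return paths, meta_path
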