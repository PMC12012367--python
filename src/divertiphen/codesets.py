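"""Declarative code-set registry parameterizing the phenotyper.

The severity rules never hard-code ICD/CPT lists; they look events up in
eight named :class:`CodeSet` s (diagnosis sets for diverticulosis,
diverticulitis and their union, plus imaging/endoscopy/operative
procedure sets). A demo registry ships with the package, but
institutional lists vary, so users are expected to supply their own via
:func:`load_codesets`.

Matching is dot-insensitive and case-insensitive: ``K57.32`` and
``k5732`` compare equal. A pattern ending in ``*`` matches any code with
that prefix; otherwise matching is exact. The vocabulary must always
agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ehr_core import ClinicalEvent, Vocabulary

__all__ = [
    "CodeSet",
    "CodeSetRegistry",
    "CodeSetError",
    "REQUIRED_SETS",
    "match",
    "load_codesets",
    "default_registry",
]

REQUIRED_SETS = (
    "diverticulosis_dx",
    "diverticulitis_dx",
    "diverticular_any_dx",
    "abdominal_ct",
    "lower_gi_endoscopy",
    "colectomy",
    "percutaneous_drain",
    "fistula_repair",
)


class CodeSetError(ValueError):
    """Configuration error in a code-set file."""


def _normalize(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeSet:
    """A named list of (vocabulary, pattern) entries."""

    name: str
    entries: tuple[tuple[Vocabulary, str], ...]

    def matches_code(self, vocabulary: Vocabulary, code: str) -> bool:
        norm = _normalize(code)
        for vocab, pattern in self.entries:
            if vocab is not vocabulary:
                continue
            pat = _normalize(pattern)
            if pat.endswith("*"):
                if norm.startswith(pat[:-1]):
                    return True
            elif norm == pat:
                return True
        return False


def match(code_set: CodeSet, event: ClinicalEvent) -> bool:
    """True iff the event's (vocabulary, code) hits any entry of the set."""
    return code_set.matches_code(event.vocabulary, event.code)


@dataclass
class CodeSetRegistry:
    sets: dict[str, CodeSet] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CodeSet:
        return self.sets[name]

    def validate(self) -> None:
        for name in REQUIRED_SETS:
            if name not in self.sets or not self.sets[name].entries:
                raise CodeSetError(f"required code set {name!r} missing or empty")
        # diverticular_any_dx must cover both diagnosis subsets
        any_dx = self.sets["diverticular_any_dx"]
        for sub in ("diverticulosis_dx", "diverticulitis_dx"):
            for vocab, pattern in self.sets[sub].entries:
                probe = _normalize(pattern).rstrip("*")
                if not any_dx.matches_code(vocab, probe):
                    raise CodeSetError(
                        f"diverticular_any_dx does not cover {sub} entry "
                        f"{vocab.value}:{pattern}"
                    )
        # severity logic needs a partition: no code may satisfy both subsets
        osis, itis = self.sets["diverticulosis_dx"], self.sets["diverticulitis_dx"]
        for vocab, pattern in osis.entries:
            probe = _normalize(pattern).rstrip("*")
            if itis.matches_code(vocab, probe):
                raise CodeSetError(
                    f"code pattern {vocab.value}:{pattern} matches both "
                    "diverticulosis_dx and diverticulitis_dx"
                )
        for vocab, pattern in itis.entries:
            probe = _normalize(pattern).rstrip("*")
            if osis.matches_code(vocab, probe):
                raise CodeSetError(
                    f"code pattern {vocab.value}:{pattern} matches both "
                    "diverticulosis_dx and diverticulitis_dx"
                )


def _parse_entries(name: str, raw_entries: list) -> CodeSet:
    entries = []
    for raw in raw_entries:
        try:
            vocab_str, pattern = str(raw).split(":", 1)
            entries.append((Vocabulary(vocab_str.strip()), pattern.strip()))
        except ValueError as exc:
            raise CodeSetError(f"code set {name!r}: bad entry {raw!r}") from exc
    return CodeSet(name=name, entries=tuple(entries))


def load_codesets(path: str | Path) -> CodeSetRegistry:
    """Load and validate a registry from a YAML file.

    Layout: one key per set, entries as ``"VOCAB:pattern"`` strings,
    pattern either an exact code or a prefix ending in ``*``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CodeSetError(f"{path}: expected a mapping of set name -> entry list")
    registry = CodeSetRegistry(
        sets={name: _parse_entries(name, entries) for name, entries in raw.items()}
    )
    registry.validate()
    return registry


def default_registry() -> CodeSetRegistry:
    """The bundled demo registry.

    The ICD-10 ``K57`` family is split by the "with diverticulitis"
    designation (diverticulosis = the "without diverticulitis" codes);
    the ICD-9 analog is 562.10/562.12 (diverticulosis of colon, with or
    without hemorrhage) versus 562.11/562.13 (diverticulitis). CPT lists
    for imaging/endoscopy/procedures are illustrative placeholders that
    institutional users must review against their own extracts.
    """
    path = Path(__file__).parent / "data" / "default_codesets.yaml"
    return load_codesets(path)
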