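"""ICD-10 code hierarchy and CCS grouping.

ICD-10 diagnosis codes are alphanumeric and tree-structured: a chapter
letter (A-Z) followed by digits, with a dot conventionally written after
the third character ("E10.9"). For statistical work only the letter and
the first three digits are used, which induces a four-level hierarchy:

    level 1  chapter letter        E
    level 2  letter + 1 digit      E1
    level 3  letter + 2 digits     E10
    level 4  letter + 3 digits     E109   (canonical full-depth code)

Pairwise code similarity is the level of the nearest common ancestor
(NCA) divided by the hierarchy depth (4). Codes from different chapters
share only a virtual root at level 0, so their similarity is 0.

The Clinical Classifications Software (CCS) scheme collapses ICD-10
codes into 259 clinically meaningful categories (numbered 1-259); a
patient's diagnoses become a 259-dimensional 0/1 vector. For example,
diabetes mellitus spans ICD-10 E10.x-E14.x and maps to CCS 49 (without
complications) and 50 (with complications).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Depth of the truncated ICD-10 hierarchy (chapter letter + three digits).
N_LEVELS = 4

#: Number of CCS single-level diagnosis categories.
N_CCS = 259

_CANONICAL_RE = re.compile(r"^[A-Z][0-9]{0,3}$")

#: Virtual root of the code forest; ancestor of every code, level 0.
ROOT = ""


@dataclass(frozen=True, order=True)
class ICDCode:
    """A canonical truncated ICD-10 code: chapter letter + up to 3 digits."""

    text: str

    def __post_init__(self) -> None:
        if not _CANONICAL_RE.match(self.text):
            raise ValueError(
                f"not a canonical ICD-10 code (expected [A-Z][0-9]{{0,3}}): {self.text!r}"
            )

    @property
    def level(self) -> int:
        """Hierarchy level: 1 + number of digits, in {1, 2, 3, 4}."""
        return len(self.text)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


def parse_icd_code(text: str) -> ICDCode:
    """Canonicalize a raw ICD-10 code string.

    Strips the dot and truncates to the chapter letter plus the first
    three digits ("E10.9" -> E109, "E11.90x" -> E119). Idempotent on
    canonical input.

    Raises
    ------
    ValueError
        If ``text`` is empty, does not start with A-Z, or a non-digit
        character (other than the dot) appears among the first three
        post-letter positions.
    """
    if not text:
        raise ValueError("empty ICD-10 code")
    s = text.strip().upper().replace(".", "", 1)
    if not s or not ("A" <= s[0] <= "Z"):
        raise ValueError(f"ICD-10 code must start with a letter A-Z: {text!r}")
    digits = []
    for ch in s[1:4]:
        if not ch.isdigit():
            raise ValueError(
                f"non-digit character {ch!r} among the leading digits of {text!r}"
            )
        digits.append(ch)
    return ICDCode(s[0] + "".join(digits))


def code_level(code: ICDCode) -> int:
    """Hierarchy level of a code (1 = chapter letter, 4 = full depth)."""
    return code.level


def nearest_common_ancestor(x: ICDCode, y: ICDCode) -> ICDCode | str:
    """Longest common prefix of two codes; :data:`ROOT` if chapters differ.

    The returned ancestor is itself a valid code (a prefix of both), or
    the virtual root (level 0) when the chapter letters differ.
    """
    n = 0
    for a, b in zip(x.text, y.text):
        if a != b:
            break
        n += 1
    return ROOT if n == 0 else ICDCode(x.text[:n])


def code_similarity(x: ICDCode, y: ICDCode) -> float:
    """Pairwise hierarchical code similarity: level(NCA) / 4.

    Symmetric and bounded in [0, 1]. Equals 1 only for identical
    full-depth codes; cross-chapter pairs score 0.
    """
    nca = nearest_common_ancestor(x, y)
    lvl = 0 if nca == ROOT else nca.level
    return lvl / N_LEVELS


class CCSMapping:
    """Longest-prefix ICD-10 -> CCS category crosswalk.

    Parameters
    ----------
    entries : mapping of str to int
        ICD-10 code prefixes (canonical form, e.g. "E10") to CCS
        category numbers in [1, 259]. Prefixes must be unique; lookup
        uses the longest matching prefix.
    """

    def __init__(self, entries: Mapping[str, int]):
        clean: dict[str, int] = {}
        for prefix, ccs in entries.items():
            prefix = prefix.strip().upper()
            if not _CANONICAL_RE.match(prefix):
                raise ValueError(f"invalid ICD-10 prefix in crosswalk: {prefix!r}")
            ccs = int(ccs)
            if not 1 <= ccs <= N_CCS:
                raise ValueError(f"CCS category {ccs} outside [1, {N_CCS}]")
            if prefix in clean:
                raise ValueError(f"duplicate crosswalk prefix {prefix!r}")
            clean[prefix] = ccs
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CCSMapping":
        """Load a two-column tab-separated crosswalk (`icd_prefix<TAB>ccs`)."""
        entries: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:2] != ["icd_prefix", "ccs"]:
                raise ValueError(
                    f"crosswalk header must be 'icd_prefix<TAB>ccs', got {header}"
                )
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                prefix, ccs = line.split("\t")[:2]
                if prefix in entries:
                    raise ValueError(f"duplicate crosswalk prefix {prefix!r}")
                entries[prefix] = int(ccs)
        return cls(entries)

    @classmethod
    def bundled(cls) -> "CCSMapping":
        """The packaged fixture crosswalk covering the synthetic code universe."""
        ref = resources.files("patsim.data").joinpath("ccs_crosswalk.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def map_to_ccs(
    code: ICDCode, mapping: CCSMapping, *, strict: bool = False
) -> int | None:
    """Map a canonical code to its CCS category by longest-prefix match.

    Returns ``None`` for unmapped codes (with a logged warning) unless
    ``strict`` is set, in which case a :class:`KeyError` is raised.
    Real crosswalks are incomplete, so silent failure is not an option;
    callers must handle the ``None`` outcome.
    """
    for end in range(len(code.text), 0, -1):
        ccs = mapping.entries.get(code.text[:end])
        if ccs is not None:
            return ccs
    if strict:
        raise KeyError(f"ICD-10 code {code.text} has no CCS crosswalk entry")
    logger.warning("ICD-10 code %s not in CCS crosswalk; dropped", code.text)
    return None


def ccs_vector(
    codes: Iterable[ICDCode], mapping: CCSMapping, *, strict: bool = False
) -> np.ndarray:
    """Collapse a diagnosis code set to a 259-dimensional 0/1 vector.

    Entry ``k-1`` is 1 iff some code maps to CCS category ``k`` (set
    semantics: repeated categories stay 1). Unmapped codes are dropped
    (or raise, under ``strict``) via :func:`map_to_ccs`.
    """
    vec = np.zeros(N_CCS, dtype=np.int8)
    for code in codes:
        ccs = map_to_ccs(code, mapping, strict=strict)
        if ccs is not None:
            vec[ccs - 1] = 1
    return vec
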