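"""Suicide-attempt case definition for ICD-9 and ICD-10-CM code strings.

A code denotes a suicide attempt when it falls in one of the validated
families below.  Matching operates on the *normalized* code string —
uppercased with the period removed — and character positions are always
counted in that normalized string, which mirrors how ICD-10-CM codes are
stored in most data warehouses.

ICD-9 families (prefix match): E95*, 965*, 967*, 969*, 881*.

ICD-10-CM families:

* ``X71``–``X83`` (intentional self-harm by mechanism), prefix match;
* ``T14.91`` (suicide attempt, unspecified means), prefix match;
* poisoning/toxic-effect families ``T36``–``T50`` and ``T51``–``T65``,
  where the *intent* character must be ``'2'`` (intentional self-harm).
  For most codes the intent character sits in the 6th normalized
  position; for stems without a further agent subdivision (e.g. T39.9,
  T42.7, T58.0) the intent character sits in the 5th position.  The
  exact stems using the 5th position are enumerated in
  :data:`T36_T50_FIFTH_POSITION_STEMS` and
  :data:`T51_T65_FIFTH_POSITION_STEMS`.

Codes too short to carry the required intent character do not match; no
padding is applied.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Union

__all__ = [
    "ICDCode",
    "METHOD_CATEGORIES",
    "matches_case_definition",
    "classify_method",
    "flag_subsequent_encounter",
    "load_method_table",
    "normalize_code",
]

#: The six suicide-attempt method categories; ``other`` covers codes with
#: no specified method.
METHOD_CATEGORIES = (
    "poisoning",
    "cutting_piercing",
    "hanging_strangulation_suffocation",
    "jumping",
    "firearm",
    "other",
)

ICD9_PREFIXES = ("E95", "965", "967", "969", "881")

X_CODE_PREFIXES = tuple(f"X{i}" for i in range(71, 84))

#: T36-T50 stems whose intent character is the 5th normalized character.
T36_T50_FIFTH_POSITION_STEMS = frozenset(
    {"T369", "T379", "T399", "T414", "T427", "T439", "T459", "T479", "T499"}
)

#: T51-T65 stems whose intent character is the 5th normalized character.
T51_T65_FIFTH_POSITION_STEMS = frozenset(
    {
        "T519", "T529", "T539", "T549", "T569", "T579",
        "T580", "T581", "T589", "T599", "T609",
        "T610", "T611", "T619", "T629", "T639",
        "T640", "T648", "T659",
    }
)


def normalize_code(raw: str) -> str:
    """Uppercase a code string and strip periods and surrounding blanks."""
    return raw.strip().replace(".", "").upper()


@dataclass(frozen=True)
class ICDCode:
    """An ICD code string as recorded, plus its version and normalized form."""

    raw: str
    version: int
    normalized: str = field(init=False)

    def __post_init__(self) -> None:
        if not isinstance(self.raw, str) or not self.raw.strip():
            raise ValueError(f"empty or non-string ICD code: {self.raw!r}")
        if self.version not in (9, 10):
            raise ValueError(
                f"unknown ICD version {self.version!r} for code {self.raw!r}; "
                "expected 9 or 10"
            )
        object.__setattr__(self, "normalized", normalize_code(self.raw))


CodeLike = Union[ICDCode, str]


def _coerce(code: CodeLike, version: Optional[int]) -> ICDCode:
    if isinstance(code, ICDCode):
        return code
    if version is None:
        raise TypeError("version is required when passing a raw code string")
    return ICDCode(code, int(version))


def _t_family_match(norm: str) -> bool:
    """Intent-character rule for the T36–T65 poisoning/toxic-effect families."""
    if len(norm) < 3 or norm[0] != "T" or not norm[1:3].isdigit():
        return False
    family = int(norm[1:3])
    if 36 <= family <= 50:
        fifth_position_stems = T36_T50_FIFTH_POSITION_STEMS
    elif 51 <= family <= 65:
        fifth_position_stems = T51_T65_FIFTH_POSITION_STEMS
    else:
        return False
    if norm[:4] in fifth_position_stems:
        return len(norm) >= 5 and norm[4] == "2"
    return len(norm) >= 6 and norm[5] == "2"


def matches_case_definition(code: CodeLike, version: Optional[int] = None) -> bool:
    """True iff the code denotes a suicide attempt under the case definition.

    Parameters
    ----------
    code
        An :class:`ICDCode`, or a raw code string (``version`` then required).
    version
        9 or 10; ignored when ``code`` is an :class:`ICDCode`.
    """
    c = _coerce(code, version)
    norm = c.normalized
    if c.version == 9:
        return norm.startswith(ICD9_PREFIXES)
    if norm.startswith(X_CODE_PREFIXES):
        return True
    if norm.startswith("T1491"):
        return True
    return _t_family_match(norm)


def flag_subsequent_encounter(code: CodeLike, version: Optional[int] = None) -> bool:
    """True iff the code carries the ICD-10-CM 7th-character ``'D'`` extension.

    The ``'D'`` extension marks a *subsequent encounter* for a condition
    already under active treatment — a strong hint that the code re-documents
    an earlier event rather than a new one.  ICD-9 codes have no encounter
    extension and always return False.
    """
    c = _coerce(code, version)
    return c.version == 10 and len(c.normalized) >= 7 and c.normalized[6] == "D"


# ---------------------------------------------------------------------------
# Method classification


def load_method_table(path: Optional[str] = None) -> Mapping[tuple[int, str], str]:
    """Load a (version, code-prefix) → method-category mapping table.

    The table is a two-key CSV with header ``icd_version,prefix,category``;
    prefixes are matched against normalized code strings, longest prefix
    wins.  With ``path=None`` the bundled default table is returned.  Sites
    with local coding conventions can supply their own file.
    """
    if path is None:
        source = resources.files("sadedup.data").joinpath("method_map.csv")
        text = source.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    table: dict[tuple[int, str], str] = {}
    for row in rows:
        category = row["category"].strip()
        if category not in METHOD_CATEGORIES:
            raise ValueError(f"unknown method category {category!r} in mapping table")
        table[(int(row["icd_version"]), normalize_code(row["prefix"]))] = category
    return table


@functools.lru_cache(maxsize=1)
def _default_table() -> Mapping[tuple[int, str], str]:
    return load_method_table(None)


def classify_method(
    code: CodeLike,
    version: Optional[int] = None,
    table: Optional[Mapping[tuple[int, str], str]] = None,
) -> str:
    """Return the suicide-attempt method category for a matched code.

    Total on matched codes: any code absent from the mapping table falls
    back to ``"other"`` (which by convention includes codes with no
    specified method, e.g. T14.91*).
    """
    c = _coerce(code, version)
    if table is None:
        table = _default_table()
    best: Optional[str] = None
    best_len = -1
    for (ver, prefix), category in table.items():
        if ver == c.version and c.normalized.startswith(prefix) and len(prefix) > best_len:
            best, best_len = category, len(prefix)
    return best if best is not None else "other"
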