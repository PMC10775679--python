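"""Phecode vocabulary: ordered code list, exclusion sets, sex restrictions.

Phecodes aggregate related ICD diagnosis codes for phenome-wide analyses.
Each phecode may carry an *exclusion set* — codes whose presence disqualifies
a non-case from serving as a control — and a sex restriction. The vocabulary
fixes a total ordering (numerically by code) that defines the positions of
the many-hot diagnosis encoding and the one-hot query encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_ANY = "any"
SEX_FEMALE = "female"
SEX_MALE = "male"
_VALID_SEX = {SEX_ANY, SEX_FEMALE, SEX_MALE}


class VocabularyError(ValueError):
    """Raised for inconsistent vocabulary definitions or unknown phecodes."""


def _numeric_key(code: str) -> tuple[float, str]:
    try:
        return (float(code), code)
    except ValueError:
        return (float("inf"), code)


@dataclass(frozen=True)
class PhecodeVocabulary:
    """Ordered phecode vocabulary with per-code exclusions and sex restrictions.

    Parameters
    ----------
    codes
        Phecode identifiers, stored sorted numerically (lexicographic
        fallback for non-numeric identifiers). Must be unique.
    exclusions
        Mapping phecode -> frozenset of exclusion phecodes. Every exclusion
        must itself be in the vocabulary and must not equal its own phecode.
    sex_restriction
        Mapping phecode -> "any" | "female" | "male". Missing keys mean "any".
    """

    codes: tuple[str, ...]
    exclusions: dict[str, frozenset[str]] = field(default_factory=dict)
    sex_restriction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(dict.fromkeys(self.codes), key=_numeric_key))
        if len(ordered) != len(self.codes):
            raise VocabularyError("phecode identifiers must be unique")
        object.__setattr__(self, "codes", ordered)
        index = {c: i for i, c in enumerate(ordered)}
        object.__setattr__(self, "_index", index)
        excl = {}
        for code, ex in self.exclusions.items():
            if code not in index:
                raise VocabularyError(f"exclusion entry for unknown phecode {code!r}")
            ex = frozenset(ex) - {code}
            missing = ex - index.keys()
            if missing:
                raise VocabularyError(
                    f"exclusions of {code!r} not in vocabulary: {sorted(missing)}"
                )
            excl[code] = ex
        object.__setattr__(self, "exclusions", excl)
        for code, sex in self.sex_restriction.items():
            if code not in index:
                raise VocabularyError(f"sex restriction for unknown phecode {code!r}")
            if sex not in _VALID_SEX:
                raise VocabularyError(f"invalid sex restriction {sex!r} for {code!r}")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def index(self, code: str) -> int:
        """Position of ``code`` in the many-hot / one-hot orderings."""
        try:
            return self._index[code]
        except KeyError:
            raise VocabularyError(f"phecode {code!r} not in vocabulary") from None

    def exclusions_of(self, code: str) -> frozenset[str]:
        self.index(code)
        return self.exclusions.get(code, frozenset())

    def sex_of(self, code: str) -> str:
        self.index(code)
        return self.sex_restriction.get(code, SEX_ANY)

    def masked_positions(self, query: str) -> np.ndarray:
        """Positions hidden for ``query``: the query itself plus its exclusions."""
        pos = [self.index(query)] + [self.index(c) for c in self.exclusions_of(query)]
        return np.unique(np.asarray(pos, dtype=np.intp))

    def exclusion_matrix(self) -> np.ndarray:
        """Boolean (V, V) matrix: entry [q, e] true iff e is an exclusion of q."""
        v = len(self)
        mat = np.zeros((v, v), dtype=bool)
        for code, ex in self.exclusions.items():
            qi = self._index[code]
            for e in ex:
                mat[qi, self._index[e]] = True
        return mat

    @classmethod
    def from_definitions(cls, defs: pd.DataFrame) -> "PhecodeVocabulary":
        """Build from a definition table (phecode, exclusions, sex).

        ``exclusions`` is a semicolon-separated string (may be empty/NaN);
        ``sex`` is one of any/female/male (missing -> any).
        """
        required = {"phecode"}
        if not required <= set(defs.columns):
            raise VocabularyError(f"definition table must have columns {sorted(required)}")
        codes = [str(c) for c in defs["phecode"]]
        exclusions: dict[str, frozenset[str]] = {}
        sex: dict[str, str] = {}
        for _, row in defs.iterrows():
            code = str(row["phecode"])
            raw = row.get("exclusions", "")
            if isinstance(raw, str) and raw.strip():
                exclusions[code] = frozenset(s.strip() for s in raw.split(";") if s.strip())
            s = row.get("sex", SEX_ANY)
            if isinstance(s, str) and s.strip() and s != SEX_ANY:
                sex[code] = s.strip()
        return cls(tuple(codes), exclusions, sex)

    def to_definitions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phecode": self.codes,
                "exclusions": [";".join(sorted(self.exclusions_of(c))) for c in self.codes],
                "sex": [self.sex_of(c) for c in self.codes],
            }
        )
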