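"""Response coding for typed picture-naming data.

Raw typed responses are first normalised (whitespace collapse, lowercase,
spelling-variant clustering) and then assigned exactly one coding
category:

``invalid``
    "DK" and equivalents — the participant signalled they did not know.
``unknown``
    Not understandable in relation to the image and absent from the
    dictionary (blank responses, random strings).
``idiosyncratic``
    Understandable but not in the dictionary (typically multi-word
    compounds unique to a few participants).
``non_object``
    In the dictionary but not the name of a single object (activities,
    materials, adjectives...), listed in a curated table.
``physically_dissimilar``
    A dictionary word that cannot describe the depicted object
    (associative responses), flagged per (image, name) pair.
``valid_name``
    Everything else.

Whether a response is "understandable in relationship to the image" is a
human judgement; the pipeline makes it declarative through curated
resource tables rather than attempting to compute it.  A response absent
from the dictionary counts as understandable when it is listed in the
``understandable`` table, or when it is a multi-word compound whose
component words are all dictionary words.

Each coded response carries inclusion flags for the downstream
computations: invalid responses stay in the name-agreement denominator
but are excluded from the H-statistic and from RT; unknown responses are
excluded from RT only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TrialResponse",
    "CodedResponse",
    "CodingResources",
    "CodingReport",
    "CODE_CATEGORIES",
    "normalize_spelling",
    "code_response",
    "code_trials",
    "coding_report",
]

CODE_CATEGORIES = (
    "valid_name",
    "invalid",
    "unknown",
    "idiosyncratic",
    "non_object",
    "physically_dissimilar",
)

#: Default tokens signalling an explicit "don't know" response.
DEFAULT_DK_TOKENS = frozenset(
    {"dk", "d k", "d.k.", "n/a", "na", "dont know", "don't know"}
)

# include_in_{agreement, H, rt, weighted(provisional)} per category.
# Agreement counts every response; H drops invalid; RT drops invalid and
# unknown; the weighted flag is provisional pending the singleton and
# frequency-availability exclusions applied at norming time.
_FLAGS = {
    "valid_name": (True, True, True, True),
    "invalid": (True, False, False, False),
    "unknown": (True, True, False, True),
    "idiosyncratic": (True, True, True, True),
    "non_object": (True, True, True, True),
    "physically_dissimilar": (True, True, True, True),
}

_PUNCT_ONLY = re.compile(r"^[\W_]*$")


@dataclass(frozen=True)
class TrialResponse:
    """One raw naming trial: who saw what image and what they typed."""

    participant_id: str
    image_id: str
    object_id: str
    list_id: str
    raw_response: str
    rt_ms: float

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError(f"rt_ms must be positive, got {self.rt_ms}")


@dataclass(frozen=True)
class CodedResponse:
    """A trial after spelling normalisation and category coding."""

    trial: TrialResponse
    canonical_name: str | None
    code: str
    include_in_agreement: bool
    include_in_H: bool
    include_in_rt: bool
    include_in_weighted: bool


@dataclass
class CodingResources:
    """Curated tables driving response coding.

    ``variant_map`` maps misspelt variants to their canonical name;
    ``dictionary`` is the set of in-dictionary wordforms (including
    multi-word names); ``non_object_list`` holds dictionary words that do
    not name a single object; ``dissimilar_overrides`` holds (image_id,
    name) pairs judged physically dissimilar from the depicted object;
    ``dk_tokens`` are explicit don't-know responses; ``understandable``
    optionally lists out-of-dictionary strings judged understandable
    (hence idiosyncratic rather than unknown).
    """

    variant_map: dict[str, str] = field(default_factory=dict)
    dictionary: set[str] = field(default_factory=set)
    non_object_list: set[str] = field(default_factory=set)
    dissimilar_overrides: set[tuple[str, str]] = field(default_factory=set)
    dk_tokens: frozenset[str] = DEFAULT_DK_TOKENS
    understandable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dk_tokens = frozenset(self.dk_tokens)
        bad = [
            v
            for v in self.variant_map.values()
            if v in self.variant_map and self.variant_map[v] != v
        ]
        if bad:
            raise ValueError(
                f"variant_map values must be canonical, but {sorted(set(bad))!r} "
                "are themselves variants"
            )

    # -- TSV round trip ----------------------------------------------------
    def to_dir(self, path) -> None:
        """Write the resource tables as TSV files under ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            sorted(self.variant_map.items()), columns=["variant", "canonical"]
        ).to_csv(path / "variant_map.tsv", sep="\t", index=False)
        for name, values in [
            ("dictionary", self.dictionary),
            ("non_object_list", self.non_object_list),
            ("dk_tokens", self.dk_tokens),
            ("understandable", self.understandable),
        ]:
            (path / f"{name}.tsv").write_text(
                "\n".join(sorted(values)) + ("\n" if values else ""),
                encoding="utf-8",
            )
        pd.DataFrame(
            sorted(self.dissimilar_overrides), columns=["image_id", "name"]
        ).to_csv(path / "dissimilar_overrides.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "CodingResources":
        path = Path(path)
        if not path.is_dir():
            raise FileNotFoundError(f"coding resources directory not found: {path}")
        vm = pd.read_csv(path / "variant_map.tsv", sep="\t", dtype=str)
        variant_map = dict(zip(vm["variant"], vm["canonical"]))

        def read_set(name: str) -> set[str]:
            p = path / f"{name}.tsv"
            if not p.exists():
                return set()
            return {ln for ln in p.read_text(encoding="utf-8").splitlines() if ln}

        ov = pd.read_csv(path / "dissimilar_overrides.tsv", sep="\t", dtype=str)
        overrides = set(zip(ov["image_id"], ov["name"]))
        dk = read_set("dk_tokens") or set(DEFAULT_DK_TOKENS)
        return cls(
            variant_map=variant_map,
            dictionary=read_set("dictionary"),
            non_object_list=read_set("non_object_list"),
            dissimilar_overrides=overrides,
            dk_tokens=frozenset(dk),
            understandable=read_set("understandable"),
        )


def normalize_spelling(raw_response: str, variant_map: Mapping[str, str]) -> str:
    """Normalise a raw typed response to its canonical spelling.

    Surrounding whitespace is stripped, internal runs of whitespace
    collapsed to single spaces, and the string lowercased (simple
    lowercase — diacritics are preserved).  If the result is a known
    spelling variant it is replaced by its canonical group name;
    otherwise it passes through unchanged for later coding.
    """
    s = " ".join(str(raw_response).split()).lower()
    return variant_map.get(s, s)


def _classify(image_id: str, name: str, resources: CodingResources) -> str:
    if name in resources.dk_tokens:
        return "invalid"
    if _PUNCT_ONLY.match(name):
        # blank or pure-punctuation responses are "unknown", not invalid
        return "unknown"
    if name in resources.dictionary:
        if name in resources.non_object_list:
            return "non_object"
        if (image_id, name) in resources.dissimilar_overrides:
            return "physically_dissimilar"
        return "valid_name"
    words = name.split()
    understandable = name in resources.understandable or (
        len(words) > 1 and all(w in resources.dictionary for w in words)
    )
    return "idiosyncratic" if understandable else "unknown"


def code_response(trial: TrialResponse, resources: CodingResources) -> CodedResponse:
    """Code one trial: normalise its spelling and assign a category.

    Decision order: explicit don't-know tokens are ``invalid``; blank or
    unintelligible out-of-dictionary strings are ``unknown``;
    understandable out-of-dictionary responses are ``idiosyncratic``;
    dictionary words are ``non_object`` or ``physically_dissimilar`` when
    so listed, otherwise ``valid_name``.
    """
    name = normalize_spelling(trial.raw_response, resources.variant_map)
    code = _classify(trial.image_id, name, resources)
    agr, h, rt, wt = _FLAGS[code]
    return CodedResponse(
        trial=trial,
        canonical_name=None if code == "invalid" else name,
        code=code,
        include_in_agreement=agr,
        include_in_H=h,
        include_in_rt=rt,
        include_in_weighted=wt,
    )


def code_trials(trials: pd.DataFrame, resources: CodingResources) -> pd.DataFrame:
    """Code a trial-level table, adding canonical names, codes and flags.

    ``trials`` must carry ``image_id`` and ``raw_response`` columns; all
    input columns are preserved in the output.
    """
    if not {"image_id", "raw_response"}.issubset(trials.columns):
        missing = {"image_id", "raw_response"} - set(trials.columns)
        raise ValueError(f"trials table lacks required columns: {sorted(missing)}")
    names, codes = [], []
    for image_id, raw in zip(trials["image_id"], trials["raw_response"]):
        raw = "" if pd.isna(raw) else raw
        name = normalize_spelling(raw, resources.variant_map)
        code = _classify(str(image_id), name, resources)
        names.append(None if code == "invalid" else name)
        codes.append(code)
    out = trials.copy()
    out["canonical_name"] = names
    out["code"] = pd.Categorical(codes, categories=list(CODE_CATEGORIES))
    flags = pd.DataFrame(
        [_FLAGS[c] for c in codes],
        columns=[
            "include_in_agreement",
            "include_in_H",
            "include_in_rt",
            "include_in_weighted",
        ],
        index=out.index,
    )
    return pd.concat([out, flags], axis=1)


@dataclass(frozen=True)
class CodingReport:
    """Counts and percentages per coding category.

    The invalid percentage is relative to all responses; the equivocal
    categories are reported relative to valid (= total - invalid)
    responses, following the convention of the norms.  Percentages are
    rounded to two decimals.
    """

    n_total: int
    n_invalid: int
    pct_invalid: float
    n_valid: int
    n_unknown: int
    pct_unknown: float
    n_idiosyncratic: int
    pct_idiosyncratic: float
    n_non_object: int
    pct_non_object: float
    n_physically_dissimilar: int
    pct_physically_dissimilar: float
    n_valid_known: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def coding_report(codes: Iterable[str] | pd.DataFrame) -> CodingReport:
    """Summarise coded responses into category counts and percentages."""
    if isinstance(codes, pd.DataFrame):
        codes = codes["code"]
    counts = pd.Series(list(codes)).value_counts().to_dict()
    unknown_cats = set(counts) - set(CODE_CATEGORIES)
    if unknown_cats:
        raise ValueError(f"unknown code categories: {sorted(unknown_cats)}")
    n_total = int(sum(counts.values()))
    if n_total == 0:
        raise ValueError("no coded responses to report on")
    n_invalid = int(counts.get("invalid", 0))
    n_valid = n_total - n_invalid

    def pct(n: int, denom: int) -> float:
        return round(100.0 * n / denom, 2) if denom else 0.0

    n_unknown = int(counts.get("unknown", 0))
    n_idio = int(counts.get("idiosyncratic", 0))
    n_nonobj = int(counts.get("non_object", 0))
    n_diss = int(counts.get("physically_dissimilar", 0))
    return CodingReport(
        n_total=n_total,
        n_invalid=n_invalid,
        pct_invalid=pct(n_invalid, n_total),
        n_valid=n_valid,
        n_unknown=n_unknown,
        pct_unknown=pct(n_unknown, n_valid),
        n_idiosyncratic=n_idio,
        pct_idiosyncratic=pct(n_idio, n_valid),
        n_non_object=n_nonobj,
        pct_non_object=pct(n_nonobj, n_valid),
        n_physically_dissimilar=n_diss,
        pct_physically_dissimilar=pct(n_diss, n_valid),
        n_valid_known=n_valid - n_unknown,
    )
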