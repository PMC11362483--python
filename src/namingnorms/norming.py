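"""Per-image normed variables for picture-naming studies.

Given coded trial-level responses, this module computes the published
image-level norms: the distribution of produced names, the modal name and
its agreement percentage, the H-statistic (Shannon entropy of the valid
name distribution, in bits) and its normalised counterpart, Zipf word
frequencies looked up from a subtitle-style corpus lexicon, word lengths,
and production-weighted average frequency/length over all retained names.

Conventions used throughout:

* *valid* responses are all responses except those coded ``invalid``
  ("DK" and equivalents).  Name agreement is computed against **all**
  responses (invalid included in the denominator); the H-statistic is
  computed over valid responses only.
* Missing lexical values (a name absent from the frequency lexicon) are
  represented by ``NaN``, never by zero: a Zipf of 0 would be a real —
  extremely low — frequency, not an unknown one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EmptyImageError",
    "LexiconEntry",
    "Lexicon",
    "NameDistribution",
    "tally_names",
    "modal_name",
    "h_statistic",
    "normalised_h",
    "zipf_unigram",
    "zipf_bigram",
    "word_length",
    "weighted_lexical",
    "compile_image_norms",
]

#: Marker for unavailable lexical values.
MISSING = float("nan")


class EmptyImageError(ValueError):
    """Raised when an image has no responses at all."""


# ---------------------------------------------------------------------------
# Zipf frequencies
# ---------------------------------------------------------------------------

def zipf_unigram(raw_count: float, corpus_tokens: float) -> float:
    """Zipf frequency of a wordform: log10 of its frequency per billion tokens.

    The Zipf scale runs from roughly 1 (one occurrence per 100 million
    tokens; very rare) to roughly 7 (one per 100 tokens; extremely common).

    Parameters
    ----------
    raw_count:
        Raw number of occurrences of the wordform in the corpus.  A count
        of 0 yields ``NaN`` (missing frequency), not a Zipf of 0.
    corpus_tokens:
        Total token count of the corpus.
    """
    if corpus_tokens <= 0:
        raise ValueError("corpus_tokens must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    if raw_count == 0:
        return MISSING
    return math.log10(raw_count * 1e9 / corpus_tokens)


def zipf_bigram(raw_bigram_count: float, corpus_tokens: float) -> float:
    """Zipf frequency of a two-word name from its raw bigram count.

    Same scale and formula as :func:`zipf_unigram`, applied to the raw
    corpus count of the bigram.
    """
    return zipf_unigram(raw_bigram_count, corpus_tokens)


@dataclass(frozen=True)
class LexiconEntry:
    """A wordform with its raw corpus count and derived Zipf value."""

    wordform: str
    raw_count: int
    corpus_tokens: int

    @property
    def zipf(self) -> float:
        return zipf_unigram(self.raw_count, self.corpus_tokens)


class Lexicon:
    """Word-frequency lexicon mapping wordforms to Zipf frequencies.

    Holds raw unigram counts and, separately, raw counts for two-word
    names ("bigrams", keyed by the space-separated form).  Lookups for
    names containing a space consult the bigram table.
    """

    def __init__(
        self,
        unigram_counts: Mapping[str, int],
        corpus_tokens: int,
        bigram_counts: Mapping[str, int] | None = None,
    ) -> None:
        if corpus_tokens <= 0:
            raise ValueError("corpus_tokens must be positive")
        self.unigram_counts = dict(unigram_counts)
        self.bigram_counts = dict(bigram_counts or {})
        self.corpus_tokens = int(corpus_tokens)

    def __contains__(self, name: str) -> bool:
        table = self.bigram_counts if " " in name else self.unigram_counts
        return name in table

    def __len__(self) -> int:
        return len(self.unigram_counts) + len(self.bigram_counts)

    def raw_count(self, name: str) -> int:
        table = self.bigram_counts if " " in name else self.unigram_counts
        return table.get(name, 0)

    def zipf(self, name: str) -> float:
        """Zipf frequency of ``name``; ``NaN`` when absent from the lexicon."""
        count = self.raw_count(name)
        if count <= 0:
            return MISSING
        if " " in name:
            return zipf_bigram(count, self.corpus_tokens)
        return zipf_unigram(count, self.corpus_tokens)

    def entries(self) -> list[LexiconEntry]:
        out = [
            LexiconEntry(w, c, self.corpus_tokens)
            for w, c in self.unigram_counts.items()
        ]
        out += [
            LexiconEntry(w, c, self.corpus_tokens)
            for w, c in self.bigram_counts.items()
        ]
        return out

    # -- TSV round trip ----------------------------------------------------
    @classmethod
    def from_tsv(
        cls,
        unigram_path,
        corpus_tokens: int,
        bigram_path=None,
    ) -> "Lexicon":
        """Read a lexicon from TSV file(s) with columns wordform, raw_count."""
        uni = pd.read_csv(unigram_path, sep="\t", dtype={"wordform": str})
        unigrams = dict(zip(uni["wordform"], uni["raw_count"].astype(int)))
        bigrams = {}
        if bigram_path is not None:
            bi = pd.read_csv(bigram_path, sep="\t", dtype={"wordform": str})
            bigrams = dict(zip(bi["wordform"], bi["raw_count"].astype(int)))
        return cls(unigrams, corpus_tokens, bigrams)

    def to_tsv(self, unigram_path, bigram_path=None) -> None:
        pd.DataFrame(
            sorted(self.unigram_counts.items()), columns=["wordform", "raw_count"]
        ).to_csv(unigram_path, sep="\t", index=False)
        if bigram_path is not None:
            pd.DataFrame(
                sorted(self.bigram_counts.items()), columns=["wordform", "raw_count"]
            ).to_csv(bigram_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Name distributions
# ---------------------------------------------------------------------------

@dataclass
class NameDistribution:
    """Production-frequency distribution of names for one image.

    ``counts`` covers valid responses only (each key is a canonical name,
    each value the number of participants who produced it);
    ``n_all_responses`` additionally counts invalid responses, and is the
    denominator for name agreement.
    """

    image_id: str
    counts: dict[str, int]
    n_all_responses: int

    def __post_init__(self) -> None:
        self.counts = {n: int(c) for n, c in self.counts.items() if c > 0}
        if self.n_valid > self.n_all_responses:
            raise ValueError(
                f"image {self.image_id!r}: valid count {self.n_valid} exceeds "
                f"total responses {self.n_all_responses}"
            )

    @property
    def n_valid(self) -> int:
        return sum(self.counts.values())

    @property
    def k(self) -> int:
        """Number of distinct names produced (production frequency >= 1)."""
        return len(self.counts)

    def proportions(self) -> dict[str, float]:
        n = self.n_valid
        return {name: c / n for name, c in self.counts.items()}


def tally_names(coded: pd.DataFrame, image_id: str | None = None) -> NameDistribution:
    """Tally the name distribution for one image from its coded responses.

    Parameters
    ----------
    coded:
        Coded responses for a single image; must carry ``canonical_name``
        and ``include_in_H`` columns (the latter is False for invalid
        responses, which enter ``n_all_responses`` but not the counts).
    image_id:
        Identifier recorded on the distribution; inferred from the
        ``image_id`` column when omitted.
    """
    if len(coded) == 0:
        raise EmptyImageError(f"image {image_id!r} has no responses")
    if image_id is None:
        ids = coded["image_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"expected responses of one image, got {sorted(ids)}")
        image_id = ids[0]
    valid = coded[coded["include_in_H"].astype(bool)]
    counts = valid["canonical_name"].value_counts().to_dict()
    return NameDistribution(
        image_id=str(image_id), counts=counts, n_all_responses=len(coded)
    )


def modal_name(
    dist: NameDistribution, lexicon: Lexicon | None = None
) -> tuple[str, float, int]:
    """Modal name, name agreement (%) and modal production frequency.

    The modal name is the most frequently produced name.  Agreement is the
    percentage of **all** responses (invalid included in the denominator)
    that match it.  Ties are broken in favour of the name with the higher
    Zipf frequency (when a lexicon is supplied), then alphabetically, so
    the result is deterministic.
    """
    if dist.n_valid < 1:
        raise EmptyImageError(f"image {dist.image_id!r} has no valid responses")

    def sort_key(name: str):
        z = lexicon.zipf(name) if lexicon is not None else MISSING
        if math.isnan(z):
            z = -math.inf
        return (-dist.counts[name], -z, name)

    winner = min(dist.counts, key=sort_key)
    count = dist.counts[winner]
    agreement = 100.0 * count / dist.n_all_responses
    return winner, agreement, count


def h_statistic(dist: NameDistribution) -> float:
    """Naming uncertainty H = sum_i p_i * log2(1 / p_i), in bits.

    ``p_i`` is the proportion of valid responses producing name *i*.
    H = 0 means unanimity (all participants gave the same name); larger
    values mean greater diversity in naming, with an upper bound of
    log2(k) for k distinct names.
    """
    if dist.n_valid < 1:
        raise EmptyImageError(f"image {dist.image_id!r} has no valid responses")
    n = dist.n_valid
    return float(-sum((c / n) * math.log2(c / n) for c in dist.counts.values())) + 0.0


def normalised_h(dist: NameDistribution) -> float:
    """H rescaled to [0, 1] by its maximum for the image's valid-response count.

    Defined as H / log2(n_valid); 0 when the image has a single valid
    response (or a single distinct name).  Dividing by the sample-size
    bound makes uncertainty comparable across images with different
    numbers of valid responses.
    """
    n = dist.n_valid
    if n < 2:
        return 0.0
    return h_statistic(dist) / math.log2(n)


# ---------------------------------------------------------------------------
# Word lengths and weighted lexical variables
# ---------------------------------------------------------------------------

def word_length(name: str) -> int:
    """Number of letters in a (spelling-corrected) name, excluding spaces."""
    n = sum(1 for ch in name if not ch.isspace())
    if n == 0:
        raise ValueError("cannot compute word length of an empty name")
    return n


def weighted_lexical(
    dist: NameDistribution,
    lexicon: Lexicon,
    min_count: int = 2,
) -> tuple[float, float]:
    """Production-weighted average Zipf frequency and word length.

    Names produced only once for the image (singletons — typically
    equivocal responses unrepresentative of what the image activates) are
    excluded.  For the weighted frequency, names without an available
    lexicon frequency are additionally excluded; the weighted length
    requires no lexicon entry.  Weights are renormalised over the
    retained names, so each result is a convex combination of the
    retained names' values.  Returns ``(NaN, NaN)``-style missing markers
    when no name survives the exclusions.
    """
    retained = {
        name: c
        for name, c in dist.counts.items()
        if c >= min_count and name.strip() != ""
    }

    def convex(values: dict[str, float]) -> float:
        if not values:
            return MISSING
        total = sum(retained[n] for n in values)
        return sum(retained[n] * v for n, v in values.items()) / total

    zipfs = {
        name: z
        for name in retained
        if not math.isnan(z := lexicon.zipf(name))
    }
    lengths = {name: float(word_length(name)) for name in retained}
    return convex(zipfs), convex(lengths)


# ---------------------------------------------------------------------------
# Norms table
# ---------------------------------------------------------------------------

#: Numeric columns summarised Table-1 style (mean, SD, median, min, max).
SUMMARY_VARIABLES = [
    "agreement_pct",
    "h_bits",
    "h_normalised",
    "mean_rt_ms",
    "modal_production_frequency",
    "modal_zipf",
    "modal_length_letters",
    "weighted_zipf",
    "weighted_length_letters",
]


def _alternative_names(dist: NameDistribution, modal: str) -> str:
    """Non-modal names in descending production frequency, as name:count pairs."""
    alts = sorted(
        ((n, c) for n, c in dist.counts.items() if n != modal),
        key=lambda nc: (-nc[1], nc[0]),
    )
    return ";".join(f"{n}:{c}" for n, c in alts)


def compile_image_norms(
    coded: pd.DataFrame,
    lexicon: Lexicon,
    rt_means: Mapping[str, float] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the full per-image norms table plus a Table-1 style summary.

    Parameters
    ----------
    coded:
        Coded trial-level responses for all images (columns ``image_id``,
        ``object_id``, ``kind``, ``canonical_name``, ``include_in_H``).
    lexicon:
        Frequency lexicon for Zipf lookups and modal tie-breaks.
    rt_means:
        Mapping of image_id to mean recognition RT (ms) after trimming;
        images absent from the mapping get a missing marker.

    Returns
    -------
    (norms, summary):
        ``norms`` has one row per image; ``summary`` reports mean, SD,
        median, min and max for each numeric normed variable.  Values are
        kept at full precision; rounding happens only at serialisation.
    """
    rt_means = dict(rt_means)
    rows = []
    for image_id, group in coded.groupby("image_id", sort=True):
        dist = tally_names(group, image_id=image_id)
        modal, agreement, modal_count = modal_name(dist, lexicon)
        wz, wl = weighted_lexical(dist, lexicon)
        rows.append(
            {
                "image_id": image_id,
                "object_id": group["object_id"].iloc[0],
                "kind": group["kind"].iloc[0] if "kind" in group else "",
                "modal_name": modal,
                "alternative_names": _alternative_names(dist, modal),
                "agreement_pct": agreement,
                "modal_production_frequency": modal_count,
                "h_bits": h_statistic(dist),
                "h_normalised": normalised_h(dist),
                "mean_rt_ms": rt_means.get(image_id, MISSING),
                "modal_zipf": lexicon.zipf(modal),
                "modal_length_letters": word_length(modal) if modal.strip() else MISSING,
                "weighted_zipf": wz,
                "weighted_length_letters": wl,
                "n_all_responses": dist.n_all_responses,
                "n_valid": dist.n_valid,
                "k_names": dist.k,
            }
        )
    norms = pd.DataFrame(rows)

    summary = pd.DataFrame(
        {
            "mean": norms[SUMMARY_VARIABLES].mean(),
            "sd": norms[SUMMARY_VARIABLES].std(ddof=1),
            "median": norms[SUMMARY_VARIABLES].median(),
            "min": norms[SUMMARY_VARIABLES].min(),
            "max": norms[SUMMARY_VARIABLES].max(),
        }
    )
    summary.index.name = "variable"
    return norms, summary
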