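"""Synthetic timed picture-naming studies with known ground truth.

Emulates the design of a web-based typed naming study: 800 images of 200
objects (four photographs per object, half natural kinds, half
artefacts) divided over 16 lists of 50 trials; 60 participants each
complete a contiguous wrap-around block of 4-16 lists starting from one
of four rotation entry points.

Each object carries a latent distribution over candidate names drawn
from a Dirichlet with a small concentration (so uncertainty varies from
unanimity to high diversity); each of its images perturbs that base
distribution with a second, high-concentration Dirichlet re-draw centred
on it.  Naming uncertainty therefore varies at the object rather than
the image level, and every image has a known true H (entropy in bits)
and a known true production-weighted Zipf frequency.

Recognition latencies follow a linear model in the image's true naming
uncertainty (or, alternatively, its true weighted Zipf frequency):
``rt = intercept + slope * predictor + participant effect + residual``,
with Gaussian participant effects and residuals, and rare extreme
outliers injected by replacement (> 10 s or < 200 ms) rather than by
heavy tails, so that the RT trimming stages have exact ground-truth
removal counts.

A small fraction of trials receives, instead of a sampled name, an
explicit don't-know token, a gibberish string, an idiosyncratic
compound, a non-object word, or a physically dissimilar word; sampled
names are additionally misspelt at a configurable rate using an explicit
deterministic variant table, which makes spelling normalisation exactly
invertible.  The generator returns the coding resources (dictionary,
variant map, category word lists) that restore the ground truth.

All randomness derives from a single integer master seed through
``numpy.random.SeedSequence`` spawning, so identical seeds yield
byte-identical studies.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coding import CodingResources
from .norming import Lexicon

__all__ = [
    "StudyDesign",
    "RTModel",
    "NoiseConfig",
    "LatentObject",
    "ListRotation",
    "GroundTruth",
    "SimulatedStudy",
    "DesignError",
    "make_synthetic_lexicon",
    "build_list_rotation",
    "generate_latent_objects",
    "generate_trials",
    "simulate_study",
]


class DesignError(ValueError):
    """Raised when study-design counts are infeasible."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Counts and rotation structure of the naming study.

    The defaults mirror the norming study the generator emulates:
    60 participants, 16 lists of 50 trials covering 800 images
    (200 objects x 4 images), participants completing between 4 and 16
    lists (mean target 8.62) from starting lists 0, 4, 8 or 12.
    """

    n_participants: int = 60
    n_lists: int = 16
    list_length: int = 50
    n_objects: int = 200
    images_per_object: int = 4
    min_lists_per_participant: int = 4
    max_lists_per_participant: int = 16
    mean_lists_target: float = 8.62
    starting_lists: tuple[int, ...] = (0, 4, 8, 12)

    def __post_init__(self) -> None:
        if self.n_lists * self.list_length != self.n_objects * self.images_per_object:
            raise DesignError(
                f"{self.n_lists} lists x {self.list_length} trials != "
                f"{self.n_objects} objects x {self.images_per_object} images"
            )
        if self.images_per_object < 2 or self.n_lists < 2:
            raise DesignError("need >= 2 images per object and >= 2 lists")
        if not (
            1
            <= self.min_lists_per_participant
            <= self.mean_lists_target
            <= self.max_lists_per_participant
            <= self.n_lists
        ):
            raise DesignError("list-count range must satisfy min <= mean <= max <= n_lists")
        if any(not 0 <= s < self.n_lists for s in self.starting_lists):
            raise DesignError("starting lists out of range")

    @property
    def n_images(self) -> int:
        return self.n_objects * self.images_per_object


@dataclass(frozen=True)
class RTModel:
    """Linear latency model.

    ``predictor`` selects the image-level quantity driving mean RT:
    ``"entropy"`` uses the image's true H in bits with ``slope_per_H``
    (ms/bit); ``"weighted_zipf"`` uses the true production-weighted Zipf
    frequency with ``slope_per_zipf`` (ms per Zipf unit, typically
    negative — frequent names are recognised faster).  Participant
    effects and trial residuals are Gaussian (extremes come only from
    explicit outlier injection, never from heavy tails, so trimming has
    exact ground-truth counts), and clean latencies are clamped to
    [floor_ms, ceil_ms] so injected outliers are the only trials outside
    the trimming bounds.
    """

    intercept: float = 800.0
    slope_per_H: float = 185.27
    slope_per_zipf: float = -145.24
    predictor: str = "entropy"
    participant_sd: float = 150.0
    residual_sd: float = 300.0
    p_long_outlier: float = 0.00376
    p_short_outlier: float = 0.00123
    floor_ms: float = 250.0
    ceil_ms: float = 9_500.0

    def __post_init__(self) -> None:
        if self.participant_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for p in (self.p_long_outlier, self.p_short_outlier):
            if not 0 <= p <= 1:
                raise ValueError("outlier probabilities must lie in [0, 1]")
        if self.predictor not in ("entropy", "weighted_zipf"):
            raise ValueError(f"unknown RT predictor {self.predictor!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-trial probabilities of non-modal response behaviours.

    The category probabilities are absolute per-trial probabilities and
    must sum to less than 1; the remainder of trials sample a name from
    the image's latent distribution, which is then misspelt with
    probability ``p_misspelling``.  Rates default to the empirical
    category prevalences of the study being emulated (~2.2% invalid,
    small equivocal rates).
    """

    p_invalid: float = 0.0218
    p_unknown: float = 0.0006
    p_idiosyncratic: float = 0.0228
    p_non_object: float = 0.0095
    p_dissimilar: float = 0.0005
    p_misspelling: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = (
            self.p_invalid,
            self.p_unknown,
            self.p_idiosyncratic,
            self.p_non_object,
            self.p_dissimilar,
            self.p_misspelling,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if (
            self.p_invalid
            + self.p_unknown
            + self.p_idiosyncratic
            + self.p_non_object
            + self.p_dissimilar
        ) >= 1:
            raise ValueError("category probabilities must sum to < 1")


# ---------------------------------------------------------------------------
# Synthetic lexicon
# ---------------------------------------------------------------------------

_ONSETS = list("bdfgklmnprstvz")
_VOWELS = list("aeiou")
_GIBBERISH_LETTERS = list("qxzjwkvh")

#: English filler vocabularies for the non-name response categories.  They
#: are placed in the coding dictionary but not in the frequency lexicon.
MODIFIER_WORDS = (
    "big", "small", "old", "red", "green", "round", "flat", "long",
    "broken", "shiny", "striped", "double",
)
NON_OBJECT_WORDS = (
    "skiing", "flying", "sailing", "health", "old", "sea", "beach",
    "gold", "wicker", "wood", "metal", "nature",
)
DISSIMILAR_WORDS = (
    "helmet", "carrot", "sunflower", "kettle", "ribbon", "anchor",
    "lantern", "marble",
)


def _pseudoword(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 4))
    s = "".join(
        rng.choice(_ONSETS) + rng.choice(_VOWELS) for _ in range(n_syll)
    )
    if rng.random() < 0.4:
        s += rng.choice(_ONSETS)
    return s


def make_synthetic_lexicon(
    n_words: int = 2400,
    corpus_tokens: int = 201_000_000,
    seed: int | np.random.SeedSequence = 0,
    zipf_mean: float = 4.0,
    zipf_sd: float = 0.9,
) -> Lexicon:
    """Generate a SUBTLEX-style lexicon of unique pseudo-words.

    Raw counts are back-computed from Zipf values drawn from a truncated
    normal (mean ~4, the typical Zipf of concrete object names), over a
    corpus of ~201 million tokens (the scale of a subtitle corpus).
    Bigram names and their raw counts are added later by
    :func:`generate_latent_objects` when two-word names are created.
    """
    rng = np.random.default_rng(seed)
    words: list[str] = []
    seen: set[str] = set(MODIFIER_WORDS) | set(NON_OBJECT_WORDS) | set(DISSIMILAR_WORDS)
    while len(words) < n_words:
        w = _pseudoword(rng)
        if w not in seen:
            seen.add(w)
            words.append(w)
    zipfs = np.clip(rng.normal(zipf_mean, zipf_sd, size=n_words), 1.0, 6.8)
    counts = {
        w: max(1, int(round(10**z * corpus_tokens / 1e9)))
        for w, z in zip(words, zipfs)
    }
    return Lexicon(counts, corpus_tokens)


# ---------------------------------------------------------------------------
# Latent objects
# ---------------------------------------------------------------------------

@dataclass
class LatentObject:
    """Ground-truth naming distribution for one object and its images."""

    object_id: str
    kind: str
    candidate_names: tuple[str, ...]
    name_probs_per_image: np.ndarray  # (images_per_object, k)
    true_h_per_image: np.ndarray  # bits
    true_weighted_zipf_per_image: np.ndarray

    def __post_init__(self) -> None:
        sums = self.name_probs_per_image.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError(f"object {self.object_id}: probabilities must sum to 1")
        check = np.array(
            [_entropy_bits(p) for p in self.name_probs_per_image]
        )
        if not np.allclose(check, self.true_h_per_image, atol=1e-9):
            raise ValueError(f"object {self.object_id}: true_h mismatch")


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def generate_latent_objects(
    n_objects: int,
    images_per_object: int,
    concentration: float,
    lexicon: Lexicon,
    seed: int | np.random.SeedSequence = 0,
    n_candidates: int = 8,
    image_concentration: float = 150.0,
    p_bigram_name: float = 0.12,
    bigram_zipf_mean: float = 2.8,
    bigram_zipf_sd: float = 0.6,
) -> list[LatentObject]:
    """Draw latent name distributions for each object and image.

    Each object receives ``n_candidates`` candidate names, disjoint
    across objects, drawn from the lexicon (a fraction become two-word
    names, whose raw bigram counts are added to the lexicon's bigram
    table).  The object's base distribution is a single draw from a
    symmetric Dirichlet(``concentration``); each image's vector is a
    re-draw from Dirichlet(``image_concentration`` * base), a small
    perturbation that keeps uncertainty an object-level property (the
    per-object minimum and maximum normalised H correlate strongly).

    Smaller ``concentration`` yields sparser base distributions — lower
    average entropy spread over a wide range including near-unanimity.
    """
    if concentration <= 0 or image_concentration <= 0:
        raise ValueError("concentrations must be positive")
    if len(lexicon.unigram_counts) == 0:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(seed)
    pool = list(lexicon.unigram_counts)
    # worst case every candidate is a bigram consuming two pool words
    if n_objects * n_candidates * 2 > len(pool):
        raise ValueError(
            f"lexicon too small: {n_objects} objects x {n_candidates} candidates "
            f"need up to {n_objects * n_candidates * 2} words, have {len(pool)}"
        )
    order = rng.permutation(len(pool))
    cursor = 0

    def next_word() -> str:
        nonlocal cursor
        w = pool[order[cursor]]
        cursor += 1
        return w

    objects = []
    for i in range(n_objects):
        names = []
        for _ in range(n_candidates):
            if n_candidates > 1 and rng.random() < p_bigram_name:
                big = f"{next_word()} {next_word()}"
                z = rng.normal(bigram_zipf_mean, bigram_zipf_sd)
                lexicon.bigram_counts[big] = max(
                    1, int(round(10 ** np.clip(z, 0.5, 5.0) * lexicon.corpus_tokens / 1e9))
                )
                names.append(big)
            else:
                names.append(next_word())
        k = len(names)
        if k == 1:
            base = np.ones(1)
            probs = np.ones((images_per_object, 1))
        else:
            base = rng.dirichlet(np.full(k, concentration))
            probs = rng.dirichlet(
                np.maximum(image_concentration * base, 1e-6),
                size=images_per_object,
            )
        probs = probs / probs.sum(axis=1, keepdims=True)
        zipfs = np.array([lexicon.zipf(n) for n in names])
        objects.append(
            LatentObject(
                object_id=f"obj{i:03d}",
                kind="natural" if i < n_objects // 2 else "artefact",
                candidate_names=tuple(names),
                name_probs_per_image=probs,
                true_h_per_image=np.array([_entropy_bits(p) for p in probs]),
                true_weighted_zipf_per_image=probs @ zipfs,
            )
        )
    return objects


# ---------------------------------------------------------------------------
# List rotation
# ---------------------------------------------------------------------------

@dataclass
class ListRotation:
    """Assignment of images to lists and of list sequences to participants."""

    image_to_list: dict[str, int]
    list_images: dict[int, list[str]]
    participant_lists: dict[str, tuple[int, ...]]
    participant_start: dict[str, int]


def build_list_rotation(
    design: StudyDesign,
    image_object_map: dict[str, str],
    seed: int | np.random.SeedSequence = 0,
) -> ListRotation:
    """Pseudo-randomly divide images over lists and rotate lists over participants.

    Every image lands in exactly one list; the images of each object are
    spread over as many distinct lists as possible (always >= 2), which a
    greatest-remaining-capacity greedy guarantees.  Each participant is
    assigned one of the starting lists (balanced across participants)
    and completes a contiguous wrap-around sequence of lists whose
    length is drawn from a shifted binomial matching the configured
    min/max range and mean target.
    """
    if len(image_object_map) != design.n_images:
        raise DesignError(
            f"expected {design.n_images} images, got {len(image_object_map)}"
        )
    rng = np.random.default_rng(seed)

    by_object: dict[str, list[str]] = {}
    for image, obj in image_object_map.items():
        by_object.setdefault(obj, []).append(image)
    for obj, images in by_object.items():
        if len(images) != design.images_per_object:
            raise DesignError(
                f"object {obj} has {len(images)} images, "
                f"expected {design.images_per_object}"
            )

    capacity = np.full(design.n_lists, design.list_length)
    image_to_list: dict[str, int] = {}
    list_images: dict[int, list[str]] = {i: [] for i in range(design.n_lists)}
    objects = sorted(by_object)
    for obj in rng.permutation(objects):
        used: set[int] = set()
        for image in sorted(by_object[obj]):
            # prefer unused lists with the greatest remaining capacity
            candidates = [
                l for l in range(design.n_lists) if capacity[l] > 0 and l not in used
            ]
            if not candidates:
                candidates = [l for l in range(design.n_lists) if capacity[l] > 0]
            if not candidates:
                raise DesignError("list capacities exhausted; design infeasible")
            cap_max = max(capacity[l] for l in candidates)
            best = [l for l in candidates if capacity[l] == cap_max]
            choice = int(rng.choice(best))
            image_to_list[image] = choice
            list_images[choice].append(image)
            capacity[choice] -= 1
            used.add(choice)
        if len({image_to_list[i] for i in by_object[obj]}) < 2:
            raise DesignError(f"object {obj} confined to a single list")

    # participants: balanced starting lists, wrap-around contiguous windows
    participants = [f"p{i:03d}" for i in range(design.n_participants)]
    starts = [
        design.starting_lists[i % len(design.starting_lists)]
        for i in range(design.n_participants)
    ]
    starts = [starts[i] for i in rng.permutation(design.n_participants)]
    span = design.max_lists_per_participant - design.min_lists_per_participant
    if span == 0:
        n_lists_each = np.full(design.n_participants, design.min_lists_per_participant)
    else:
        p = (design.mean_lists_target - design.min_lists_per_participant) / span
        n_lists_each = design.min_lists_per_participant + rng.binomial(
            span, p, size=design.n_participants
        )
    participant_lists = {}
    participant_start = {}
    for pid, start, n in zip(participants, starts, n_lists_each):
        participant_lists[pid] = tuple(
            (start + j) % design.n_lists for j in range(int(n))
        )
        participant_start[pid] = int(start)
    return ListRotation(
        image_to_list=image_to_list,
        list_images=list_images,
        participant_lists=participant_lists,
        participant_start=participant_start,
    )


# ---------------------------------------------------------------------------
# Spelling variants
# ---------------------------------------------------------------------------

def _variant_candidates(name: str):
    """Deterministic misspelling candidates for a canonical name."""
    first = name.split(" ")[0]
    rest = name[len(first):]
    for i, ch in enumerate(first[1:], start=1):
        if ch in "aeiou":
            yield first[:i] + first[i + 1:] + rest  # drop a vowel
            break
    yield first + first[-1] + rest  # double the final letter of word 1
    yield first[0] + first + rest  # stutter the initial letter


def build_variant_table(
    canonical_names: list[str], forbidden: set[str]
) -> dict[str, str]:
    """Map one deterministic misspelling to each canonical name.

    Variants are produced by explicit string transformations (vowel
    deletion, letter doubling), never random edits, so normalisation is
    exactly invertible.  Candidates colliding with dictionary words,
    canonical names or already-assigned variants are skipped.
    """
    table: dict[str, str] = {}
    taken = set(forbidden) | set(canonical_names)
    for name in canonical_names:
        for cand in _variant_candidates(name):
            if cand != name and cand not in taken and cand not in table:
                table[cand] = name
                taken.add(cand)
                break
    return table


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "participant_id",
    "list_id",
    "trial_index",
    "image_id",
    "object_id",
    "kind",
    "raw_response",
    "rt_ms",
]

_DK_CHOICES = ("DK", "dk", "n/a", "dont know")


@dataclass
class GroundTruth:
    """Latent quantities recorded alongside the generated trials."""

    true_h: dict[str, float]
    true_weighted_zipf: dict[str, float]
    category_counts: Counter
    n_long_injected: int
    n_short_injected: int
    trial_category: list[str] = field(repr=False, default_factory=list)
    trial_true_name: list = field(repr=False, default_factory=list)


def _gibberish(rng: np.random.Generator, dictionary: set[str]) -> str:
    while True:
        s = "".join(rng.choice(_GIBBERISH_LETTERS, size=int(rng.integers(5, 8))))
        if s not in dictionary:
            return s


def generate_trials(
    design: StudyDesign,
    latent_objects: list[LatentObject],
    rt_model: RTModel,
    noise: NoiseConfig,
    rotation: ListRotation,
    lexicon: Lexicon,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, CodingResources, GroundTruth]:
    """Simulate every trial of the study.

    Each trial samples a response category (invalid / unknown /
    idiosyncratic / non-object / dissimilar / name) per
    :class:`NoiseConfig`; name responses sample from the image's latent
    vector and are misspelt at the configured rate.  Latencies follow
    :class:`RTModel`, with extreme outliers injected by replacement.
    Returns the trial table, the coding resources that exactly restore
    the ground truth, and the :class:`GroundTruth` record.
    """
    if seed is None:
        seed = noise.seed if noise.seed is not None else 0
    rng = np.random.default_rng(seed)

    image_objects: dict[str, LatentObject] = {}
    image_index: dict[str, int] = {}
    for obj in latent_objects:
        for j in range(design.images_per_object):
            image_id = f"{obj.object_id}_img{j}"
            image_objects[image_id] = obj
            image_index[image_id] = j

    canonical = sorted({n for o in latent_objects for n in o.candidate_names})
    dictionary = (
        set(lexicon.unigram_counts)
        | set(lexicon.bigram_counts)
        | set(canonical)
        | set(MODIFIER_WORDS)
        | set(NON_OBJECT_WORDS)
        | set(DISSIMILAR_WORDS)
    )
    variant_map = build_variant_table(canonical, forbidden=dictionary)
    variants_of: dict[str, list[str]] = {}
    for var, canon in variant_map.items():
        variants_of.setdefault(canon, []).append(var)

    cum = np.cumsum(
        [
            noise.p_invalid,
            noise.p_unknown,
            noise.p_idiosyncratic,
            noise.p_non_object,
            noise.p_dissimilar,
        ]
    )
    truth = GroundTruth(
        true_h={
            img: float(obj.true_h_per_image[image_index[img]])
            for img, obj in image_objects.items()
        },
        true_weighted_zipf={
            img: float(obj.true_weighted_zipf_per_image[image_index[img]])
            for img, obj in image_objects.items()
        },
        category_counts=Counter(),
        n_long_injected=0,
        n_short_injected=0,
    )
    dissimilar_overrides: set[tuple[str, str]] = set()

    rows = []
    for pid in sorted(rotation.participant_lists):
        p_effect = rng.normal(0.0, rt_model.participant_sd)
        for list_id in rotation.participant_lists[pid]:
            images = rotation.list_images[list_id]
            order = rng.permutation(len(images))
            for t_idx, img_pos in enumerate(order):
                image_id = images[int(img_pos)]
                obj = image_objects[image_id]
                j = image_index[image_id]

                u = rng.random()
                if u < cum[0]:
                    category, true_name = "invalid", None
                    raw = str(rng.choice(_DK_CHOICES))
                elif u < cum[1]:
                    category, true_name = "unknown", None
                    r = rng.random()
                    raw = "" if r < 0.15 else (
                        "???" if r < 0.25 else _gibberish(rng, dictionary)
                    )
                elif u < cum[2]:
                    category = "idiosyncratic"
                    probs = obj.name_probs_per_image[j]
                    base = obj.candidate_names[int(rng.choice(len(probs), p=probs))]
                    true_name = f"{rng.choice(MODIFIER_WORDS)} {base}"
                    raw = true_name
                elif u < cum[3]:
                    category = "non_object"
                    true_name = str(rng.choice(NON_OBJECT_WORDS))
                    raw = true_name
                elif u < cum[4]:
                    category = "physically_dissimilar"
                    true_name = str(rng.choice(DISSIMILAR_WORDS))
                    dissimilar_overrides.add((image_id, true_name))
                    raw = true_name
                else:
                    category = "valid_name"
                    probs = obj.name_probs_per_image[j]
                    true_name = obj.candidate_names[int(rng.choice(len(probs), p=probs))]
                    raw = true_name
                    if variants_of.get(true_name) and rng.random() < noise.p_misspelling:
                        raw = str(rng.choice(variants_of[true_name]))
                    if rng.random() < 0.08:
                        raw = raw.capitalize()
                truth.category_counts[category] += 1
                truth.trial_category.append(category)
                truth.trial_true_name.append(true_name)

                if rt_model.predictor == "entropy":
                    mu_rt = rt_model.intercept + rt_model.slope_per_H * truth.true_h[image_id]
                else:
                    mu_rt = (
                        rt_model.intercept
                        + rt_model.slope_per_zipf * truth.true_weighted_zipf[image_id]
                    )
                resid = (
                    rng.normal(0.0, rt_model.residual_sd)
                    if rt_model.residual_sd > 0
                    else 0.0
                )
                rt = mu_rt + p_effect + resid
                rt = float(np.clip(rt, rt_model.floor_ms, rt_model.ceil_ms))

                # injections on invalid/unknown trials never reach the RT
                # pool, so only the others count as trimmable ground truth
                in_rt_pool = category not in ("invalid", "unknown")
                v = rng.random()
                if v < rt_model.p_long_outlier:
                    rt = float(rng.uniform(10_001.0, 20_000.0))
                    truth.n_long_injected += in_rt_pool
                elif v < rt_model.p_long_outlier + rt_model.p_short_outlier:
                    rt = float(rng.uniform(50.0, 199.0))
                    truth.n_short_injected += in_rt_pool

                rows.append(
                    (
                        pid,
                        f"list{list_id:02d}",
                        t_idx,
                        image_id,
                        obj.object_id,
                        obj.kind,
                        raw,
                        round(rt, 1),
                    )
                )

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    resources = CodingResources(
        variant_map=variant_map,
        dictionary=dictionary,
        non_object_list=set(NON_OBJECT_WORDS),
        dissimilar_overrides=dissimilar_overrides,
        dk_tokens=frozenset(t.lower() for t in _DK_CHOICES) | {"n/a"},
    )
    return trials, resources, truth


# ---------------------------------------------------------------------------
# One-call study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """A complete simulated study: inputs, ground truth, and all artifacts."""

    design: StudyDesign
    rt_model: RTModel
    noise: NoiseConfig
    seed: int
    lexicon: Lexicon
    latent_objects: list[LatentObject]
    rotation: ListRotation
    trials: pd.DataFrame
    resources: CodingResources
    truth: GroundTruth


def simulate_study(
    design: StudyDesign | None = None,
    rt_model: RTModel | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    concentration: float = 0.16,
    n_candidates: int = 8,
    image_concentration: float = 150.0,
    corpus_tokens: int = 201_000_000,
    n_lexicon_words: int | None = None,
) -> SimulatedStudy:
    """Generate a full synthetic naming study from one master seed.

    The master seed deterministically spawns independent streams for the
    lexicon, the latent objects, the list rotation and the trial loop,
    so any change to one stage leaves the others' draws untouched.
    """
    design = design or StudyDesign()
    rt_model = rt_model or RTModel()
    noise = noise or NoiseConfig()
    ss = np.random.SeedSequence(seed)
    s_lex, s_latent, s_rot, s_trials = ss.spawn(4)

    if n_lexicon_words is None:
        n_lexicon_words = max(400, design.n_objects * n_candidates * 2 + 100)
    lexicon = make_synthetic_lexicon(
        n_words=n_lexicon_words, corpus_tokens=corpus_tokens, seed=s_lex
    )
    latent = generate_latent_objects(
        design.n_objects,
        design.images_per_object,
        concentration,
        lexicon,
        seed=s_latent,
        n_candidates=n_candidates,
        image_concentration=image_concentration,
    )
    image_object_map = {
        f"{o.object_id}_img{j}": o.object_id
        for o in latent
        for j in range(design.images_per_object)
    }
    rotation = build_list_rotation(design, image_object_map, seed=s_rot)
    trials, resources, truth = generate_trials(
        design, latent, rt_model, noise, rotation, lexicon, seed=s_trials
    )
    return SimulatedStudy(
        design=design,
        rt_model=rt_model,
        noise=noise,
        seed=seed,
        lexicon=lexicon,
        latent_objects=latent,
        rotation=rotation,
        trials=trials,
        resources=resources,
        truth=truth,
    )
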