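"""Synthetic expression data with planted co-regulation structure.

Each module grows from an independent base profile; members derive from the
base by one of four co-regulation patterns:

* ``shifted`` — additive offset (profile + alpha),
* ``scaled`` — multiplicative factor (profile * beta, beta > 0),
* ``inverted`` — reflection about the module's operating level, which
  reverses every regulation sign,
* ``mixed`` — condition-wise mirroring about the level over persistent
  random segments, so the member tracks the base under some conditions and
  mirrors it under others.

Gaussian noise is added on top.  Background genes are independent profiles
with no planted edges.  The ground truth is the within-module clique:
every within-module pair is a positive, signed by the product of the two
members' orientations (+1 for members that track the base, -1 for inverted
members).  The first member of every module is the base profile itself, so
inverted-pattern modules contain genuinely anti-correlated pairs (two
reflections of the same base are mutually *positively* similar).

Base profiles are mean-reverting random walks.  Strong mean reversion makes
consecutive values nearly independent, so edge directions — and hence edge
angles — spread broadly over [0, 180] degrees and unrelated genes rarely
match by chance.  Zero-centred profiles emulate log-ratio expression data;
modules carrying inverted or mixed members are planted around an elevated
positive operating level instead, because mirror-image edge geometry (angle
sum near 180 degrees) only arises when profiles reflect about a positive
level — reflection about zero maps an edge onto one with the *same* angle.

All randomness flows from the single spec-level seed through spawned child
sequences, so each profile is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, GoldStandard
from .errors import ParameterError, ValidationError

__all__ = ["PatternSpec", "SyntheticDataset", "make_base_profile",
           "derive_member", "generate_dataset"]

PATTERN_KINDS = ("shifted", "scaled", "inverted", "mixed")

# profile geometry (expression units): strong mean reversion, sizeable steps
_MEAN_REVERSION = 0.3       # AR(1) coefficient toward the operating level
_STEP_SD = 150.0            # innovation sd
_MIN_STEP = 15.0            # resample until consecutive values differ by this
_ELEVATED_LO, _ELEVATED_HI = 500.0, 800.0   # operating level of inverted/mixed modules
_MIXED_SWITCH_PROB = 0.25   # per-condition probability of toggling mirror state


@dataclass
class PatternSpec:
    """Generator configuration; defaults give three clean 10-gene modules.

    ``alpha`` (expression units) bounds the per-member additive offset of
    shifted members; ``beta_scale`` (dimensionless, > 0) bounds the
    multiplicative factor of scaled members, drawn log-uniformly in
    [1/beta_scale, beta_scale]; ``noise_sd`` is the sd of the additive
    Gaussian noise in expression units — compare to the step sd of 150.
    """

    n_modules: int = 3
    genes_per_module: int = 10
    n_conditions: int = 15
    pattern_kinds: tuple[str, ...] = ("shifted", "scaled", "inverted")
    alpha: float = 50.0
    beta_scale: float = 3.0
    noise_sd: float = 5.0
    n_background_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.pattern_kinds = tuple(self.pattern_kinds)
        if self.genes_per_module < 2:
            raise ParameterError("genes_per_module must be >= 2")
        if self.n_conditions < 3:
            raise ParameterError("n_conditions must be >= 3")
        if self.beta_scale <= 0:
            raise ParameterError("beta_scale must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if len(self.pattern_kinds) != self.n_modules:
            raise ParameterError(
                f"need one pattern kind per module "
                f"({self.n_modules}), got {len(self.pattern_kinds)}"
            )
        for k in self.pattern_kinds:
            if k not in PATTERN_KINDS:
                raise ParameterError(f"unknown pattern kind '{k}'")


@dataclass
class SyntheticDataset:
    """Generated matrix plus its planted ground truth."""

    matrix: ExpressionMatrix
    truth_network: GoldStandard
    module_labels: list[list[str]]
    truth_signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.truth_signs) != self.truth_network.positives:
            raise ValidationError("truth_signs keys must equal the positive pair set")


def make_base_profile(n_conditions: int, rng: np.random.Generator,
                      level: float = 0.0) -> np.ndarray:
    """Mean-reverting random-walk profile around ``level``.

    Innovations are resampled until consecutive values differ by at least
    15 units, so no edge is degenerate.
    """
    if n_conditions < 3:
        raise ParameterError("n_conditions must be >= 3")
    values = np.empty(n_conditions)
    values[0] = level + rng.normal(0.0, _STEP_SD)
    for t in range(1, n_conditions):
        while True:
            nxt = level + _MEAN_REVERSION * (values[t - 1] - level) \
                + rng.normal(0.0, _STEP_SD)
            if abs(nxt - values[t - 1]) >= _MIN_STEP:
                break
        values[t] = nxt
    return values


def derive_member(base: np.ndarray, kind: str, alpha: float, beta_scale: float,
                  noise_sd: float, rng: np.random.Generator,
                  level: float | None = None) -> np.ndarray:
    """Derive a co-regulated member profile from a base profile.

    ``level`` is the mirror axis for the inverted and mixed kinds; it
    defaults to the base's mean.
    """
    if level is None:
        level = float(base.mean())
    if kind == "shifted":
        profile = base + alpha
    elif kind == "scaled":
        if beta_scale <= 0:
            raise ParameterError("beta_scale must be > 0")
        profile = base * beta_scale
    elif kind == "inverted":
        profile = 2.0 * level - base
    elif kind == "mixed":
        # persistent mirror-state segments: +1 tracks base, -1 mirrors it
        state = np.empty(base.size)
        s = 1.0
        for t in range(base.size):
            if t > 0 and rng.random() < _MIXED_SWITCH_PROB:
                s = -s
            state[t] = s
        profile = level + state * (base - level)
    else:
        raise ParameterError(f"unknown pattern kind '{kind}'")
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
    return profile


def generate_dataset(spec: PatternSpec) -> SyntheticDataset:
    """Generate an expression matrix with planted modules and its ground truth."""
    seeds = np.random.SeedSequence(spec.seed)
    module_seeds = seeds.spawn(spec.n_modules)
    bg_seed, = seeds.spawn(1)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    modules: list[list[str]] = []
    orientations: dict[str, int] = {}

    for m, (kind, mseed) in enumerate(zip(spec.pattern_kinds, module_seeds)):
        child = mseed.spawn(spec.genes_per_module + 1)
        level_rng = np.random.default_rng(child[0])
        level = (level_rng.uniform(_ELEVATED_LO, _ELEVATED_HI)
                 if kind in ("inverted", "mixed") else 0.0)
        base = make_base_profile(spec.n_conditions, level_rng, level=level)
        members: list[str] = []
        for g in range(spec.genes_per_module):
            gid = f"M{m + 1}G{g + 1}"
            rng = np.random.default_rng(child[g + 1])
            if g == 0:
                # the base itself anchors the module (noise only)
                profile = derive_member(base, "shifted", 0.0, 1.0,
                                        spec.noise_sd, rng)
                orientations[gid] = 1
            else:
                a = rng.uniform(-spec.alpha, spec.alpha)
                b = float(np.exp(rng.uniform(-np.log(spec.beta_scale),
                                             np.log(spec.beta_scale)))) \
                    if spec.beta_scale != 1.0 else 1.0
                profile = derive_member(base, kind, a, b, spec.noise_sd, rng,
                                        level=level)
                orientations[gid] = -1 if kind == "inverted" else 1
            members.append(gid)
            gene_ids.append(gid)
            rows.append(profile)
        modules.append(members)

    if spec.n_background_genes > 0:
        bg_children = bg_seed.spawn(spec.n_background_genes)
        for g in range(spec.n_background_genes):
            gid = f"BG{g + 1}"
            gene_ids.append(gid)
            rng = np.random.default_rng(bg_children[g])
            walk = make_base_profile(spec.n_conditions, rng)
            if spec.noise_sd > 0:
                walk = walk + rng.normal(0.0, spec.noise_sd, size=walk.shape)
            rows.append(walk)

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        condition_ids=[f"C{t + 1}" for t in range(spec.n_conditions)],
        values=np.vstack(rows),
    )
    positives: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], int] = {}
    for members in modules:
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                pair = tuple(sorted((members[x], members[y])))
                positives.add(pair)
                signs[pair] = orientations[members[x]] * orientations[members[y]]
    gold = GoldStandard(gene_ids=list(gene_ids), positives=positives)
    return SyntheticDataset(matrix=matrix, truth_network=gold,
                            module_labels=modules, truth_signs=signs)
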