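"""Built-in models and generators.

The open Michaelis-Menten (OMM) variants and the fumarase mechanism are
transcribed from their printed reaction lists; each fixture pairs the
model with the partition of its derivation strategy. The apoptosis-scale
xEARM model is NOT bundled: it ships as a loader plus schema validator
for a user-transcribed reaction document (58 species, 115 reactions).
``random_linear_model`` emulates the first-order benchmark ensembles
(six species, 10-20 reactions, weakly connected by rejection sampling),
and ``toy_switch`` is a small positive-feedback module with a dose
threshold used by the perturbation-analysis tests; its threshold values
are internal ground truth established by grid scans, nothing more.
"""

from __future__ import annotations

import random

from .model import MassActionModel, parse_model
from .substitution import PartitionMap, introduce_pseudospecies

__all__ = [
    "FIXTURE_NAMES",
    "fixture",
    "random_linear_model",
    "toy_switch",
    "toy_switch_values",
    "load_xearm",
    "validate_xearm",
    "XEARM_N_SPECIES",
    "XEARM_N_REACTIONS",
]

# Open Michaelis-Menten: enzyme-substrate binding, dissociation, catalysis,
# plus zero-order substrate synthesis and first-order product degradation.
# Reaction order fixes the Y indexing of the rate constants (k1..k5).
OMM_DOC = """\
# open Michaelis-Menten system
species: E S ES P
E + S -> ES ; k1
ES -> E + S ; k2
ES -> E + P ; k3
0 -> S ; k4
P -> 0 ; k5
"""

# variant with catalysis proportional to the square of the complex
OMM4_DOC = """\
# open Michaelis-Menten, superlinear catalysis
species: E S ES P
E + S -> ES ; k1
ES -> E + S ; k2
ES -> E + P ; k3 order(ES)=2
0 -> S ; k4
P -> 0 ; k5
"""

# fumarase / malate synthesis: the enzyme binds fumarate (F) and hydrogen
# (H) in either order, then hydroxyl (OH), then releases malate (M).
# Five enzyme forms, four substrates, six reversible reactions.
FUM_DOC = """\
# fumarase mechanism, all reactions reversible
species: E EF EH EFH EX F H OH M
E + F <-> EF ; k1f, k1r
E + H <-> EH ; k2f, k2r
EF + H <-> EFH ; k3f, k3r
EH + F <-> EFH ; k4f, k4r
EFH + OH <-> EX ; k5f, k5r
EX <-> E + M ; k6f, k6r
"""

# two-pool positive-feedback switch: inactive A converts to active B both
# autocatalytically (order 2 in B) and under catalysis by the input L;
# every species is synthesized and degraded, so the steady state is
# non-trivial and a step increase in L can flip B to the high state.
TOY_SWITCH_DOC = """\
# positive-feedback dose switch
species: A B L
0 -> A ; ksA
A -> 0 ; kdA
B -> 0 ; kdB
0 -> L ; ksL
L -> 0 ; kdL
A -> B ; kact order(A)=1 order(B)=2
B -> A ; koff
A -> B ; kin order(L)=1
"""

FUM_FROZEN = frozenset({"F", "H", "OH", "M"})

FIXTURE_NAMES = ("omm1", "omm2", "omm3", "omm4", "fum1", "fum2",
                 "toy_switch", "xearm")

XEARM_N_SPECIES = 58
XEARM_N_REACTIONS = 115


def fixture(name: str) -> tuple[MassActionModel, PartitionMap]:
    """Return a built-in model with the partition of its derivation strategy.

    omm1: homogeneous (all concentrations to P, all rate constants to Y);
    omm2: heterogeneous (enzyme kinetic constants k1-k3 forced independent);
    omm3: sublinear (synthesis constant k4 independent; pseudospecies);
    omm4: superlinear squared catalysis (complex concentration in Y;
    pseudospecies); fum1: King-Altman-style linear reduction (substrates
    frozen, enzyme concentrations in Y); fum2: general partition with the
    substrates time-varying (|Y| = 10).
    """
    if name == "omm1":
        model = parse_model(OMM_DOC, name="omm1")
        return model, PartitionMap.homogeneous(model)
    if name == "omm2":
        model = parse_model(OMM_DOC, name="omm2")
        return model, PartitionMap.from_sets(model, Y=["E", "ES", "P", "k4"])
    if name == "omm3":
        model = parse_model(OMM_DOC, name="omm3")
        pm = PartitionMap.from_sets(model, Y=["k1", "k2", "k3", "k5"])
        return introduce_pseudospecies(model, pm, "k4")
    if name == "omm4":
        model = parse_model(OMM4_DOC, name="omm4")
        pm = PartitionMap.from_sets(model, Y=["ES", "k1", "k4", "k5"])
        # the pseudospecies sits right after the complex it linearizes, so
        # both are favored to become dependent
        return introduce_pseudospecies(model, pm, "k3", index=1)
    if name == "fum1":
        model = parse_model(FUM_DOC, name="fum1")
        pm = PartitionMap.from_sets(model, Y=["E", "EF", "EH", "EFH", "EX"],
                                    frozen=FUM_FROZEN)
        return model, pm
    if name == "fum2":
        model = parse_model(FUM_DOC, name="fum2")
        pm = PartitionMap.from_sets(
            model,
            Y=["F", "H", "OH", "M", "k1r", "k2r", "k3r", "k4r", "k5r", "k6f"])
        return model, pm
    if name == "toy_switch":
        model = toy_switch()
        return model, PartitionMap.homogeneous(model)
    if name == "xearm":
        raise FileNotFoundError(
            "the xEARM model is not bundled: supplementary required. "
            "Transcribe 'xearm.mpl' into the reaction format and load it "
            "with load_xearm(path).")
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def toy_switch() -> MassActionModel:
    """The positive-feedback dose-switch module (3 species, 8 reactions)."""
    return parse_model(TOY_SWITCH_DOC, name="toy_switch")


def toy_switch_values() -> dict[str, float]:
    """Reference values for the switch's independent parameters.

    Abundances put the module in its low (off) state; the input-driven
    activation flux dominates autocatalysis there, so a sufficient step
    increase in L is required before the feedback loop fires (the grid-
    scanned threshold is near a 19-fold step under the defaults).
    """
    return {
        "A": 100.0, "B": 1.0, "L": 1.0,
        "kdA": 0.1, "kdL": 0.05,
        "kact": 1e-4, "koff": 0.11, "kin": 2e-3,
    }


def random_linear_model(n_species: int, n_reactions: int, seed: int
                        ) -> MassActionModel:
    """Random first-order model: distinct directed transitions, weakly
    connected, reproducible under *seed*.

    Edges are drawn uniformly without replacement among ordered species
    pairs; draws describing a disjoint network are rejected and redrawn
    (mirroring benchmark practice of discarding them), never repaired.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if n_reactions < n_species - 1:
        raise ValueError(
            "too few reactions for a connected network: need at least "
            f"{n_species - 1}")
    max_edges = n_species * (n_species - 1)
    if n_reactions > max_edges:
        raise ValueError(f"at most {max_edges} distinct transitions exist")
    rng = random.Random(seed)
    names = [f"S{i + 1}" for i in range(n_species)]
    pairs = [(a, b) for a in names for b in names if a != b]
    for _attempt in range(10_000):
        edges = rng.sample(pairs, n_reactions)
        # weak connectivity via union-find
        parent = {n: n for n in names}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in edges:
            parent[find(a)] = find(b)
        if len({find(n) for n in names}) == 1:
            break
    else:
        raise RuntimeError("could not draw a connected network")
    lines = [f"species: {' '.join(names)}"]
    lines += [f"{a} -> {b} ; k{i + 1}" for i, (a, b) in enumerate(edges)]
    return parse_model("\n".join(lines), name=f"random_{seed}")


def load_xearm(path: str) -> MassActionModel:
    """Load a user-transcribed xEARM reaction document and validate it.

    Raises :class:`FileNotFoundError` when the transcription is absent
    ("supplementary required") and :class:`ValueError` when the declared
    species/reaction counts do not match the published model.
    """
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise FileNotFoundError(
            f"supplementary required: cannot read xEARM transcription at "
            f"{path!r} ({exc})") from exc
    model = parse_model(text, name="xearm")
    validate_xearm(model)
    return model


def validate_xearm(model: MassActionModel) -> None:
    """Schema check: the transcription must carry the published counts."""
    if model.n_species != XEARM_N_SPECIES:
        raise ValueError(
            f"xEARM transcription declares {model.n_species} species, "
            f"expected {XEARM_N_SPECIES}")
    if model.n_reactions != XEARM_N_REACTIONS:
        raise ValueError(
            f"xEARM transcription declares {model.n_reactions} reactions, "
            f"expected {XEARM_N_REACTIONS}")
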