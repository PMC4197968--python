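"""Polypyrimidine-tract scanning and the rule-based splice-competence model.

An intron is considered to carry a usable polypyrimidine (pY) tract when a
run of at least ``min_py_run`` consecutive C/T bases occurs within the last
``py_window`` nucleotides of the intron (terminal AG included in the window;
its G breaks any run).  Introns with a poor pY tract can still be spliced
autonomously when very short, and longer ones can be rescued by an
exon-junction complex (EJC) deposited at a nearby flanking splice junction:

* AUTONOMOUS     - good pY tract, or poor pY but length < ``autonomous_max_length``;
* EJC_DEPENDENT  - otherwise, if some flanking junction's EJC deposition
                   site lies within ``rescue_distance`` nt of the intron's
                   3' splice site on the pre-mRNA;
* DEFECTIVE      - otherwise.

The EJC is deposited ``ejc_offset`` nt upstream of an exon-exon junction,
so for a downstream flanking intron separated by an exon of length L the
relevant distance is ``L - ejc_offset``, while for an upstream flanking
intron it is ``ejc_offset + L + target_intron_length``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGTN")

# Shortened D. melanogaster piwi intron 4 constructs used to probe the
# length rule: each is two fragments flanking an internal deletion.
PIWI_INT4_60NT_FRAGMENTS = (
    "GTAAGACTTTAAACTATATTTAAAT",
    "CCATAAAAAATGTAATATTTAATTATTATAAACAG",
)
PIWI_INT4_106NT_FRAGMENTS = (
    "GTAAGACTTTAAACTATATTTAAATTAACAAGCTCTTGTGTCGCAAAC",
    "GCAGTTTAGGGCGGTTTTATGGCCCATAAAAAATGTAATATTTAATTATTATAAACAG",
)
PIWI_INT4_60NT = "".join(PIWI_INT4_60NT_FRAGMENTS)
PIWI_INT4_106NT = "".join(PIWI_INT4_106NT_FRAGMENTS)


class Verdict(str, enum.Enum):
    AUTONOMOUS = "AUTONOMOUS"
    EJC_DEPENDENT = "EJC_DEPENDENT"
    DEFECTIVE = "DEFECTIVE"


@dataclass
class SpliceRuleParams:
    """Constants of the splice-competence model (all in nucleotides)."""

    min_py_run: int = 7
    py_window: int = 50
    autonomous_max_length: int = 90
    ejc_offset: int = 24
    rescue_distance: int = 250

    def __post_init__(self) -> None:
        for name in ("min_py_run", "py_window", "autonomous_max_length",
                     "ejc_offset", "rescue_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.py_window < self.min_py_run:
            raise ValueError("py_window must be >= min_py_run")


@dataclass
class FlankingJunction:
    """A flanking exon-exon junction, located by the pre-mRNA distance from
    its EJC deposition site to the target intron's 3' splice site."""

    side: str  # 'upstream' or 'downstream'
    distance: int

    def __post_init__(self) -> None:
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class ConstructDescription:
    """A reporter construct: one target intron plus optional flanking junctions."""

    construct_id: str
    intron_length: int
    py: str  # 'good' or 'poor'
    flanking: list[FlankingJunction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.py not in ("good", "poor"):
            raise ValueError(f"py must be 'good' or 'poor', got {self.py!r}")
        if self.intron_length <= 0:
            raise ValueError("intron_length must be positive")


def longest_pyrimidine_run(sequence: str, window: int) -> int:
    """Longest run of consecutive C/T within the final ``window`` characters.

    The whole sequence is scanned when shorter than the window.  N (or any
    non-pyrimidine) breaks a run; characters outside ACGTN are an error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    tail = sequence[-window:]
    best = cur = 0
    for base in tail:
        cur = cur + 1 if base in _PYRIMIDINES else 0
        if cur > best:
            best = cur
    return best


def has_py_tract(intron, params: SpliceRuleParams | None = None) -> bool:
    """True iff the intron's 3' end carries a pY run of at least
    ``params.min_py_run`` within the last ``params.py_window`` nt.

    ``intron`` may be an IntronRecord (``.sequence`` required) or a string.
    """
    params = params or SpliceRuleParams()
    seq = intron if isinstance(intron, str) else intron.sequence
    if seq is None:
        raise ValueError("intron has no sequence; load the genome first")
    return longest_pyrimidine_run(seq.upper(), params.py_window) >= params.min_py_run


def ejc_distance(side: str, exon_length: int, target_intron_length: int,
                 ejc_offset: int = 24) -> int:
    """Pre-mRNA distance from an EJC deposition site to the target 3' splice site.

    ``exon_length`` is the exon separating the target intron from the
    flanking junction.  Downstream junctions place the EJC between the
    target 3' splice site and the junction; upstream junctions place it
    beyond the intervening exon and the target intron itself.
    """
    if side == "downstream":
        return max(exon_length - ejc_offset, 0)
    if side == "upstream":
        return ejc_offset + exon_length + target_intron_length
    raise ValueError(f"invalid side {side!r}")


def predict_splice_competence(
    construct: ConstructDescription, params: SpliceRuleParams | None = None
) -> tuple[Verdict, str]:
    """Apply the splice-competence rules; returns (verdict, rule_fired)."""
    params = params or SpliceRuleParams()
    if construct.py == "good":
        return Verdict.AUTONOMOUS, "good_py_tract"
    if construct.intron_length < params.autonomous_max_length:
        return Verdict.AUTONOMOUS, f"poor_py_length_lt_{params.autonomous_max_length}"
    for junc in construct.flanking:
        if junc.distance <= params.rescue_distance:
            return Verdict.EJC_DEPENDENT, f"{junc.side}_ejc_within_{params.rescue_distance}"
    return Verdict.DEFECTIVE, "no_rescuing_junction"


def load_constructs_yaml(path: str, ejc_offset: int = 24) -> list[ConstructDescription]:
    """Read construct descriptions from a YAML list.

    Each entry needs ``id``, ``intron_length`` and ``py``; flanking
    junctions are given either with an explicit EJC ``distance`` or with an
    ``exon_spacer`` length from which the distance is derived.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    constructs = []
    for entry in entries:
        flanks = []
        for fl in entry.get("flanking", []) or []:
            if "distance" in fl:
                dist = int(fl["distance"])
            else:
                dist = ejc_distance(
                    fl["side"], int(fl["exon_spacer"]),
                    int(entry["intron_length"]), ejc_offset,
                )
            flanks.append(FlankingJunction(side=fl["side"], distance=dist))
        constructs.append(
            ConstructDescription(
                construct_id=str(entry["id"]),
                intron_length=int(entry["intron_length"]),
                py=entry["py"],
                flanking=flanks,
            )
        )
    return constructs


def predictions_to_tsv(
    constructs: Iterable[ConstructDescription],
    path: str,
    params: SpliceRuleParams | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("construct_id\tverdict\trule_fired\n")
        for c in constructs:
            verdict, rule = predict_splice_competence(c, params)
            fh.write(f"{c.construct_id}\t{verdict.value}\t{rule}\n")
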