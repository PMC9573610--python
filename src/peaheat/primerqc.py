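"""Design-rule validation for SNaPshot genotyping primers.

SNaPshot assays use a pair of peripheral PCR primers per SNP plus a
single-base-extension (SBE) primer whose 5′ poly-C/poly-T tail sets its
electrophoretic length.  This module checks primer candidates against the
usual design constraints: length 15–30 nt, GC content 40–60%, Tm 58–60 °C,
no appreciable self-complementarity, ≤ 4 complementary bases between
primers, no complementary 3′-end overlap, tailed SBE length ≥ 36 nt, and
4–6 nt length spacing between the SBE primers of adjacent loci (advisory).

Validation only — no primer design or thermodynamic nearest-neighbour
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PERIPHERAL_F = "PERIPHERAL_F"
PERIPHERAL_R = "PERIPHERAL_R"
EXTENSION = "EXTENSION"
ROLES = (PERIPHERAL_F, PERIPHERAL_R, EXTENSION)


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(_check_seq(seq)))


def gc_content(seq: str) -> float:
    """GC content in percent."""
    seq = _check_seq(seq)
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def melting_temp(seq: str) -> tuple[float, str]:
    """Primer melting temperature (°C) with the method used.

    Sequences of ≥ 14 nt use the basic GC formula
    Tm = 64.9 + 41 (GC − 16.4) / length; shorter ones fall back to the
    Wallace rule 2(A+T) + 4(G+C), flagged in the returned method string.
    """
    seq = _check_seq(seq)
    gc = sum(1 for b in seq if b in "GC")
    if len(seq) >= 14:
        return 64.9 + 41.0 * (gc - 16.4) / len(seq), "basic"
    return 2.0 * (len(seq) - gc) + 4.0 * gc, "wallace"


def max_self_complementarity(seq: str) -> int:
    """Length of the longest substring whose reverse complement also occurs in the sequence.

    Exhaustive scan over all substrings (primers are short); a hit of length
    k means the primer can fold or dimerise over a k-base stem.
    """
    seq = _check_seq(seq)
    return cross_complementarity(seq, seq)


def cross_complementarity(a: str, b: str) -> int:
    """Longest run where a substring of ``a`` is the reverse complement of a substring of ``b``."""
    a = _check_seq(a)
    rc_b = reverse_complement(b)
    # longest common substring of a and reverse_complement(b), O(len a × len b)
    best = 0
    prev = [0] * (len(rc_b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(rc_b) + 1)
        for j in range(1, len(rc_b) + 1):
            if a[i - 1] == rc_b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def three_prime_overlap(a: str, b: str) -> int:
    """Length of complementary overlap anchored at both primers' 3′ ends."""
    a = _check_seq(a)
    b = _check_seq(b)
    n = 0
    while n < min(len(a), len(b)) and a[len(a) - 1 - n] == _COMPLEMENT[b[len(b) - 1 - n]]:
        n += 1
    return n


@dataclass
class PrimerSpec:
    """One primer candidate: sequence, role, optional 5′ tail (SBE only)."""

    name: str
    sequence: str
    role: str
    tail: str = ""

    def __post_init__(self) -> None:
        self.sequence = _check_seq(self.sequence)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.tail:
            self.tail = _check_seq(self.tail)
            if self.role != EXTENSION:
                raise ValueError("only extension primers carry a tail")

    @property
    def tailed_length(self) -> int:
        return len(self.sequence) + len(self.tail)


@dataclass
class RuleResult:
    rule: str
    value: float | int | str
    passed: bool
    hard: bool = True             # hard rules fail the primer; soft ones only warn


@dataclass
class PrimerReport:
    name: str
    role: str
    rules: list[RuleResult] = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return all(r.passed for r in self.rules if r.hard)

    @property
    def warnings(self) -> list[RuleResult]:
        return [r for r in self.rules if not r.hard and not r.passed]


def validate(
    spec: PrimerSpec,
    partners: Sequence[PrimerSpec] = (),
    neighbor_lengths: Sequence[int] = (),
    self_comp_warn: int = 4,
    self_comp_fail: int = 6,
) -> PrimerReport:
    """Validate one primer against the design rules for its role.

    ``partners`` are the other primers at the same locus (for
    cross-complementarity and 3′-overlap checks); ``neighbor_lengths`` are
    the tailed SBE lengths at adjacent loci (spacing is advisory because
    adjacent lengths only *generally* differ by 4–6 nt).  Self-
    complementarity runs ≥ ``self_comp_warn`` warn, ≥ ``self_comp_fail``
    fail.
    """
    rep = PrimerReport(spec.name, spec.role)
    length = len(spec.sequence)
    rep.rules.append(RuleResult("length_15_30", length, 15 <= length <= 30))
    gc = gc_content(spec.sequence)
    rep.rules.append(RuleResult("gc_40_60", round(gc, 2), 40.0 <= gc <= 60.0))
    tm, method = melting_temp(spec.sequence)
    rep.rules.append(RuleResult(f"tm_58_60_{method}", round(tm, 2), 58.0 <= tm <= 60.0))
    sc = max_self_complementarity(spec.sequence)
    rep.rules.append(RuleResult("self_complementarity", sc, sc < self_comp_fail))
    if self_comp_warn <= sc < self_comp_fail:
        rep.rules.append(RuleResult("self_complementarity_warn", sc, False, hard=False))
    if spec.role in (PERIPHERAL_F, PERIPHERAL_R):
        rep.rules.append(RuleResult("effective_length_le_38", length, length <= 38))
    else:
        rep.rules.append(RuleResult("tailed_length_ge_36", spec.tailed_length, spec.tailed_length >= 36))
        for nl in neighbor_lengths:
            gap = abs(spec.tailed_length - nl)
            rep.rules.append(RuleResult(f"adjacent_spacing_4_6_vs_{nl}", gap, 4 <= gap <= 6, hard=False))
    for other in partners:
        cc = cross_complementarity(spec.sequence, other.sequence)
        rep.rules.append(RuleResult(f"cross_complementarity_le_4_vs_{other.name}", cc, cc <= 4))
        ov = three_prime_overlap(spec.sequence, other.sequence)
        rep.rules.append(RuleResult(f"three_prime_overlap_vs_{other.name}", ov, ov == 0))
    return rep


def report_table(reports: Sequence[PrimerReport]):
    """Flatten reports into a tidy table (one row per rule)."""
    import pandas as pd

    rows = []
    for rep in reports:
        for r in rep.rules:
            rows.append(
                {"primer": rep.name, "role": rep.role, "rule": r.rule, "value": r.value,
                 "passed": r.passed, "hard": r.hard, "overall": rep.overall}
            )
    return pd.DataFrame(rows)
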