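"""Degenerate-primer coverage screening.

PCR surveys of xmoA-type genes rely on degenerate primers written with
IUPAC ambiguity codes (R = A/G, N = any, ...).  A primer "covers" a target
when some ungapped placement on either strand matches within a mismatch
budget; a primer *pair* covers it when both sites exist in amplifiable
orientation (forward site upstream of the reverse-complemented reverse
site).  Mismatch counting is plain and position-blind (no 3'-end
weighting), and indels are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome_io import reverse_complement

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` is in the expansion of IUPAC ``code``."""
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code {code!r}")
    return base in IUPAC_SETS[code]


@dataclass
class PrimerSpec:
    name: str
    iupac_seq: str
    role: Literal["forward", "reverse"] = "forward"

    def __post_init__(self) -> None:
        self.iupac_seq = self.iupac_seq.upper().replace("U", "T")
        if len(self.iupac_seq) < 10:
            raise ValueError(f"primer {self.name}: shorter than 10 nt")
        for i, ch in enumerate(self.iupac_seq):
            if ch not in IUPAC_SETS:
                raise ValueError(
                    f"primer {self.name}: invalid IUPAC code {ch!r} at position {i}"
                )

    @property
    def degeneracy(self) -> int:
        return prod(len(IUPAC_SETS[c]) for c in self.iupac_seq)


@dataclass
class MismatchReport:
    primer_name: str
    target_id: str
    best_mismatches: int
    best_position: int
    strand: Literal["+", "-"]


# mismatch[code, base] lookup tables (bytes -> small ints)
_CODES = "ACGTRYSWKMBDHVN"
_MM = np.ones((256, 256), dtype=np.int8)
for _c in _CODES:
    for _b in "ACGT":
        _MM[ord(_c), ord(_b)] = 0 if _b in IUPAC_SETS[_c] else 1


def _scan(primer: str, target: str) -> tuple[int, int]:
    """(best mismatches, leftmost best offset) of an ungapped scan."""
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    L, n = len(p), len(t)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    mm = _MM[p[None, :], windows].sum(axis=1)
    best = int(mm.min())
    return best, int(np.argmin(mm))


def best_hit(primer: PrimerSpec, target: str, target_id: str = "") -> MismatchReport:
    """Minimum-mismatch placement of a primer over both target strands.

    A reverse-role primer anneals to the sense strand as its reverse
    complement, so it is scanned that way; forward primers scan as given.
    Both orientations are tried for both roles (minimum over all
    placements, strands, and degenerate expansions); ties break to the
    plus strand, then leftmost placement.
    """
    target = target.upper().replace("U", "T")
    if len(target) < len(primer.iupac_seq):
        raise ValueError(
            f"target ({len(target)} nt) shorter than primer {primer.name} "
            f"({len(primer.iupac_seq)} nt)"
        )
    seq = primer.iupac_seq
    if primer.role == "reverse":
        seq = reverse_complement(seq)
    fwd_mm, fwd_pos = _scan(seq, target)
    rev_mm, rev_pos = _scan(reverse_complement(seq), target)
    if fwd_mm <= rev_mm:
        return MismatchReport(primer.name, target_id, fwd_mm, fwd_pos, "+")
    return MismatchReport(primer.name, target_id, rev_mm, rev_pos, "-")


COVERAGE_COLUMNS = [
    "pair", "group", "n_targets", "n_amplified", "fraction",
    "mean_amplicon_length",
]


def coverage_table(
    primer_pairs: Sequence[tuple[PrimerSpec, PrimerSpec]],
    targets: Sequence[tuple[str, str]],
    groups: dict[str, str],
    max_mm: int,
) -> pd.DataFrame:
    """Per primer-pair × group fraction of targets amplified.

    ``targets`` are (id, sequence); ``groups`` maps target id -> group
    label.  A target counts as amplified when both primers place with at
    most ``max_mm`` mismatches each and in amplifiable order on the same
    orientation of the target (forward site strictly upstream of the
    reverse primer's annealing site).  Mean amplicon length (outer
    coordinates) is reported over amplified targets.
    """
    missing = [tid for tid, _ in targets if tid not in groups]
    if missing:
        raise ValueError(f"targets without group labels: {missing}")
    rows = []
    pair_names = []
    for fwd, rev in primer_pairs:
        pair_name = f"{fwd.name}/{rev.name}"
        pair_names.append(pair_name)
        rev_site = reverse_complement(rev.iupac_seq)
        for tid, seq in targets:
            seq = seq.upper().replace("U", "T")
            amplicon = _amplicon_length(fwd.iupac_seq, rev_site, seq, max_mm)
            if amplicon is None:
                amplicon = _amplicon_length(
                    fwd.iupac_seq, rev_site, reverse_complement(seq), max_mm
                )
            rows.append(
                {
                    "pair": pair_name,
                    "group": groups[tid],
                    "target_id": tid,
                    "amplified": amplicon is not None,
                    "amplicon_length": amplicon,
                }
            )
    hits = pd.DataFrame(rows)
    out = []
    for (pair, group), grp in hits.groupby(["pair", "group"], sort=False):
        amplified = grp["amplified"].sum()
        out.append(
            {
                "pair": pair,
                "group": group,
                "n_targets": len(grp),
                "n_amplified": int(amplified),
                "fraction": amplified / len(grp),
                "mean_amplicon_length": grp.loc[grp["amplified"], "amplicon_length"].mean(),
            }
        )
    df = pd.DataFrame(out, columns=COVERAGE_COLUMNS)
    return df.sort_values(["pair", "group"]).reset_index(drop=True)


def _amplicon_length(
    fwd_seq: str, rev_site: str, sense: str, max_mm: int
) -> int | None:
    """Outer amplicon length on one orientation, or None if not amplifiable."""
    if len(sense) < len(fwd_seq) or len(sense) < len(rev_site):
        return None
    pf = np.frombuffer(fwd_seq.encode(), dtype=np.uint8)
    pr = np.frombuffer(rev_site.encode(), dtype=np.uint8)
    t = np.frombuffer(sense.upper().encode(), dtype=np.uint8)
    wf = np.lib.stride_tricks.sliding_window_view(t, len(pf))
    wr = np.lib.stride_tricks.sliding_window_view(t, len(pr))
    f_ok = np.nonzero(_MM[pf[None, :], wf].sum(axis=1) <= max_mm)[0]
    r_ok = np.nonzero(_MM[pr[None, :], wr].sum(axis=1) <= max_mm)[0]
    if f_ok.size == 0 or r_ok.size == 0:
        return None
    f0 = int(f_ok[0])  # leftmost forward site
    r_after = r_ok[r_ok >= f0 + len(pf)]  # reverse site downstream of it
    if r_after.size == 0:
        return None
    return int(r_after[-1]) + len(pr) - f0


def read_primers_tsv(path) -> list[PrimerSpec]:
    df = pd.read_csv(path, sep="\t")
    needed = {"name", "sequence", "role"}
    if not needed <= set(df.columns):
        raise ValueError(f"primer table needs columns {sorted(needed)}")
    return [
        PrimerSpec(name=str(row["name"]), iupac_seq=row["sequence"], role=row["role"])
        for _, row in df.iterrows()
    ]
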