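"""TF/sigma-factor regulatory network tables and clustering constraints.

Regulatory background knowledge enters the pipeline as a table of
(transcription factor, sigma factor, target gene, effect) interactions in
the style of a RegulonDB export. From it we derive

* per-gene *regulatory signatures* — the set of (TF, SF, mode) combinations
  controlling a gene,
* the *combination index* mapping each (TF, SF, mode) combination to its
  target genes (the regulator/target network matrix used by the enrichment
  stage), and
* must-link constraints for constrained k-means: DEGs sharing an identical,
  non-empty signature are chained together, encoding the expectation that
  identically-regulated genes respond coherently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "Combo",
    "ConstraintSet",
    "read_network",
    "write_network",
    "build_signatures",
    "build_combination_index",
    "derive_mustlinks",
]

ACTIVATION = "activation"
REPRESSION = "repression"

_MODE_SYNONYMS = {
    "+": ACTIVATION, "activation": ACTIVATION, "activator": ACTIVATION,
    "act": ACTIVATION, "a": ACTIVATION, "positive": ACTIVATION, "pos": ACTIVATION,
    "-": REPRESSION, "−": REPRESSION, "repression": REPRESSION,
    "repressor": REPRESSION, "rep": REPRESSION, "r": REPRESSION,
    "negative": REPRESSION, "neg": REPRESSION, "inhibition": REPRESSION,
    "inhibitor": REPRESSION,
}

_HEADER_TOKENS = {"regulator", "tf", "sigma", "sigma_factor", "sf", "gene",
                  "target", "target_gene", "effect", "mode"}


class Combo(NamedTuple):
    """A (TF, SF, mode) unit of transcriptional control."""

    tf: str
    sf: str
    mode: str

    def label(self) -> str:
        sign = "+" if self.mode == ACTIVATION else "-"
        return f"{self.tf}/{self.sf}({sign})"


class Interaction(NamedTuple):
    """One regulator/sigma-factor -> target-gene edge with its sign."""

    tf: str
    sf: str
    gene: str
    mode: str

    @property
    def combo(self) -> Combo:
        return Combo(self.tf, self.sf, self.mode)


class NetworkError(ValueError):
    """Raised on malformed interaction tables."""


def _split_line(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.rstrip("\n").split(sep)]


def read_network(path: str | Path, alias_map: Mapping[str, str] | None = None) -> list[Interaction]:
    """Parse a RegulonDB-style interaction table.

    Columns: regulator, sigma factor, target gene, effect. Effect accepts
    the usual synonyms (``+``/``-``, activation/repression, ...). Rows are
    deduplicated; composite regulators (e.g. ``FlhDC``) are kept verbatim.
    An optional ``alias_map`` renames regulators (e.g. ``CRP`` ->
    ``CRP-cAMP``); default is no renaming.
    """
    path = Path(path)
    alias_map = dict(alias_map or {})
    interactions: list[Interaction] = []
    seen: set[Interaction] = set()
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh]
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not content:
        raise NetworkError(f"{path}: empty interaction table")
    start = 0
    first_fields = _split_line(content[0][1])
    if any(f.lower() in _HEADER_TOKENS for f in first_fields):
        start = 1
    for lineno, ln in content[start:]:
        fields = _split_line(ln)
        if len(fields) < 4:
            raise NetworkError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        tf, sf, gene, effect = fields[:4]
        mode = _MODE_SYNONYMS.get(effect.lower())
        if mode is None:
            raise NetworkError(f"{path}:{lineno}: unknown effect token {effect!r}")
        tf = alias_map.get(tf, tf)
        rec = Interaction(tf, sf, gene, mode)
        if rec not in seen:
            seen.add(rec)
            interactions.append(rec)
    return interactions


def write_network(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\tsigma_factor\ttarget_gene\teffect\n")
        for it in interactions:
            sign = "+" if it.mode == ACTIVATION else "-"
            fh.write(f"{it.tf}\t{it.sf}\t{it.gene}\t{sign}\n")


def build_signatures(
    interactions: Sequence[Interaction], universe: Iterable[str]
) -> dict[str, frozenset[Combo]]:
    """Map every gene of the universe to its set of controlling combinations.

    Genes without known regulation get an empty signature. Interactions
    whose target lies outside the universe are ignored (count logged).
    """
    universe = set(universe)
    combos: dict[str, set[Combo]] = {g: set() for g in universe}
    ignored = 0
    for it in interactions:
        if it.gene in combos:
            combos[it.gene].add(it.combo)
        else:
            ignored += 1
    if ignored:
        logger.info("ignored %d interaction(s) targeting genes outside the universe", ignored)
    return {g: frozenset(c) for g, c in combos.items()}


def build_combination_index(
    signatures: Mapping[str, frozenset[Combo]]
) -> dict[Combo, frozenset[str]]:
    """Invert signatures into the combination -> target-gene network matrix."""
    index: dict[Combo, set[str]] = {}
    for gene, combos in signatures.items():
        for combo in combos:
            index.setdefault(combo, set()).add(gene)
    return {c: frozenset(g) for c, g in index.items()}


@dataclass(frozen=True)
class ConstraintSet:
    """Must-link / cannot-link gene pairs for constrained clustering.

    Pairs are stored as sorted 2-tuples of gene ids. By default only
    must-links are generated (always satisfiable); cannot-links are
    supported by the clustering stage but never derived automatically.
    """

    must_links: frozenset[tuple[str, str]] = frozenset()
    cannot_links: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        both = self.must_links & self.cannot_links
        if both:
            raise ValueError(f"pairs in both must- and cannot-links: {sorted(both)[:3]}")

    @staticmethod
    def pair(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError(f"constraint pair links gene {a!r} to itself")
        return (a, b) if a < b else (b, a)

    def __len__(self) -> int:
        return len(self.must_links) + len(self.cannot_links)


def derive_mustlinks(
    signatures: Mapping[str, frozenset[Combo]],
    deg_genes: Iterable[str],
    max_pairs: int = 100_000,
) -> ConstraintSet:
    """Chain identically-regulated DEGs into must-link constraints.

    DEG genes whose signatures are identical *and non-empty* are linked in a
    spanning chain (gene-id order), so a group of size m contributes m - 1
    pairs rather than m(m-1)/2. Genes with empty signatures carry no
    evidence of co-regulation and generate no links. If the total exceeds
    ``max_pairs``, groups are added smallest-first so the largest groups are
    the ones truncated.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    degs = set(deg_genes)
    if not degs:
        raise ValueError("DEG set is empty")
    groups: dict[frozenset[Combo], list[str]] = {}
    for gene in sorted(degs):
        sig = signatures.get(gene, frozenset())
        if sig:
            groups.setdefault(sig, []).append(gene)
    pairs: list[tuple[str, str]] = []
    ordered = sorted(groups.values(), key=lambda g: (len(g), g[0]))
    for members in ordered:
        for a, b in zip(members, members[1:]):
            if len(pairs) >= max_pairs:
                break
            pairs.append(ConstraintSet.pair(a, b))
    return ConstraintSet(must_links=frozenset(pairs))
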