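"""Shorthand lipid nomenclature: parsing, serialization, class aggregation.

Untargeted lipidomics software reports identified species in a compact
shorthand, e.g. ``TG(16:0/16:1/18:3)`` (a triacylglycerol with three named
acyl chains), ``PC(34:2e)`` (an ether-linked phosphatidylcholine reported
only as a summed composition of 34 carbons and 2 double bonds), or
``Hex1Cer(d18:0/20:4)`` (a monohexosyl-ceramide whose sphingoid base carries
the di-hydroxy ``d`` prefix).  This module parses such names into structured
records and aggregates species-level abundance tables to lipid classes.

Grammar accepted (one species name)::

    name   := CLASS '(' body ')'
    body   := chain ('/' chain)*          # >=2 tokens: explicit chains
            | chain                        # 1 token: summed composition
    chain  := [sphingoid] INT ':' INT ['e']
    sphingoid := 'd' | 't'                 # di-/tri-hydroxy long-chain base

Class tokens are case-sensitive and drawn from an extensible registry.
A single token inside the parentheses is always read as a summed
composition (total carbons : total double bonds), never as one chain.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

#: token -> display name.  "ChE" is printed as "cholesterol" in some reports
#: although the abbreviation conventionally denotes cholesteryl esters; both
#: readings are kept in the display string.
DEFAULT_CLASS_REGISTRY: dict[str, str] = {
    "TG": "triacylglycerol",
    "DG": "diacylglycerol",
    "PC": "phosphatidylcholine",
    "PE": "phosphatidylethanolamine",
    "LPC": "lyso-phosphatidylcholine",
    "LPE": "lyso-phosphatidylethanolamine",
    "SM": "sphingomyelin",
    "ChE": "cholesterol / cholesteryl ester (abbreviation ambiguous)",
    "Cer": "ceramide",
    "Hex1Cer": "monohexosyl-ceramide",
}


class LipidParseError(ValueError):
    """Malformed lipid shorthand name; carries token and character offset."""

    def __init__(self, message: str, token: str, offset: int):
        super().__init__(f"{message}: {token!r} at offset {offset}")
        self.token = token
        self.offset = offset


@dataclass(frozen=True)
class Chain:
    carbons: int
    double_bonds: int
    ether: bool = False


@dataclass
class LipidSpecies:
    raw_name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    ether_linked: bool
    sphingoid_prefix: str | None = None
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chains:
            if sum(c.carbons for c in self.chains) != self.total_carbons:
                raise ValueError("chain carbons do not sum to total_carbons")
            if sum(c.double_bonds for c in self.chains) != self.total_double_bonds:
                raise ValueError("chain double bonds do not sum to total_double_bonds")
            if self.ether_linked != any(c.ether for c in self.chains):
                raise ValueError("ether_linked inconsistent with chain flags")

    def to_name(self) -> str:
        """Serialize back to shorthand; inverse of :func:`parse_lipid_name`."""
        if self.chains:
            parts = []
            for i, c in enumerate(self.chains):
                prefix = self.sphingoid_prefix if (i == 0 and self.sphingoid_prefix) else ""
                parts.append(f"{prefix}{c.carbons}:{c.double_bonds}{'e' if c.ether else ''}")
            body = "/".join(parts)
        else:
            prefix = self.sphingoid_prefix or ""
            suffix = "e" if self.ether_linked else ""
            body = f"{prefix}{self.total_carbons}:{self.total_double_bonds}{suffix}"
        return f"{self.lipid_class}({body})"

    def __str__(self) -> str:
        return self.to_name()


_CHAIN_RE = re.compile(r"^(d|t)?(\d+):(\d+)(e)?$")


def parse_lipid_name(name: str, registry: dict[str, str] | None = None) -> LipidSpecies:
    """Parse one shorthand lipid name into a :class:`LipidSpecies`.

    Raises :class:`LipidParseError` on unknown class tokens, unbalanced
    parentheses or non-numeric chain tokens, naming the offending token and
    its character offset in the stripped input.
    """
    registry = DEFAULT_CLASS_REGISTRY if registry is None else registry
    s = name.strip()
    if not s:
        raise LipidParseError("empty name", name, 0)
    open_idx = s.find("(")
    if open_idx < 0 or not s.endswith(")") or s.count("(") != 1 or s.count(")") != 1:
        raise LipidParseError("unbalanced or missing parentheses", s, max(open_idx, 0))
    cls = s[:open_idx]
    if cls not in registry:
        raise LipidParseError("unknown class token", cls, 0)
    body = s[open_idx + 1 : -1]
    tokens = body.split("/")
    parsed: list[tuple[str | None, int, int, bool]] = []
    offset = open_idx + 1
    for tok in tokens:
        m = _CHAIN_RE.match(tok)
        if m is None:
            raise LipidParseError("malformed chain token", tok, offset)
        prefix, carbons, dbonds, ether = m.groups()
        parsed.append((prefix, int(carbons), int(dbonds), ether is not None))
        offset += len(tok) + 1
    sphingoid = parsed[0][0]
    for prefix, *_ in parsed[1:]:
        if prefix is not None:
            raise LipidParseError("sphingoid prefix only allowed on the first chain", body, open_idx + 1)

    if len(parsed) == 1:
        # summed composition: totals only, no resolved chains
        _, carbons, dbonds, ether = parsed[0]
        return LipidSpecies(
            raw_name=s,
            lipid_class=cls,
            total_carbons=carbons,
            total_double_bonds=dbonds,
            ether_linked=ether,
            sphingoid_prefix=sphingoid,
            chains=[],
        )
    chains = [Chain(c, d, e) for (_, c, d, e) in parsed]
    return LipidSpecies(
        raw_name=s,
        lipid_class=cls,
        total_carbons=sum(c.carbons for c in chains),
        total_double_bonds=sum(c.double_bonds for c in chains),
        ether_linked=any(c.ether for c in chains),
        sphingoid_prefix=sphingoid,
        chains=chains,
    )


def parse_table(matrix: FeatureMatrix, registry: dict[str, str] | None = None,
                strict: bool = False) -> pd.DataFrame:
    """Parse every row name of a species table.

    Returns a DataFrame indexed like the input with columns
    ``lipid_class, total_carbons, total_double_bonds, ether_linked,
    sphingoid_prefix, n_chains``.  Unparseable rows are dropped with a
    warning (``strict=True`` raises instead).
    """
    rows, dropped = {}, []
    for fid in matrix.feature_ids:
        try:
            sp = parse_lipid_name(fid, registry)
        except LipidParseError as err:
            if strict:
                raise
            dropped.append((fid, str(err)))
            continue
        rows[fid] = {
            "lipid_class": sp.lipid_class,
            "total_carbons": sp.total_carbons,
            "total_double_bonds": sp.total_double_bonds,
            "ether_linked": sp.ether_linked,
            "sphingoid_prefix": sp.sphingoid_prefix or "",
            "n_chains": len(sp.chains),
        }
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} unparseable species (first: {dropped[0][0]!r})"
        )
    if not rows:
        raise ValueError("no row name parsed as a lipid species")
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_by_class(matrix: FeatureMatrix, mode: str = "absolute",
                       registry: dict[str, str] | None = None,
                       strict: bool = False) -> FeatureMatrix:
    """Sum species abundances to lipid classes, per sample.

    ``mode="absolute"`` returns summed class abundances;
    ``mode="fraction"`` divides by each sample's total so class fractions
    sum to 1.
    """
    if mode not in ("absolute", "fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    parsed = parse_table(matrix, registry, strict=strict)
    vals = matrix.values.loc[parsed.index]
    by_class = vals.groupby(parsed["lipid_class"]).sum()
    by_class = by_class.sort_index()
    if mode == "fraction":
        totals = by_class.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"sample(s) with non-positive total abundance: {bad[:5]}")
        by_class = by_class / totals
    out = FeatureMatrix(by_class, matrix.samples.copy())
    return out


def golden_species_names() -> list[str]:
    """The differential species names reported for the WDLPS/DDLPS contrast.

    Up in WDLPS: neutral storage lipids (DG/TG); down in WDLPS: membrane
    phospholipids and sphingolipids.  Used as a parser conformance suite.
    """
    return [
        # upregulated in WDLPS
        "DG(16:0/14:0)", "DG(16:1/14:0)", "TG(16:0e/6:0/10:1)",
        "TG(20:1/18:1/18:3)", "DG(30:3e)", "TG(16:1/14:0/18:2)",
        "TG(16:0/16:1/18:3)", "DG(38:2e)",
        # downregulated in WDLPS
        "PC(34:2e)", "PC(32:0e)", "Hex1Cer(d18:0/20:4)", "PC(40:4)",
        "PC(16:1e/20:4)", "PC(18:2e/20:4)", "PC(38:6e)", "LPE(18:1e)",
        "PC(14:1e/20:4)",
    ]
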