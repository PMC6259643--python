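"""In silico screening: substituent enumeration on a scaffold, prediction, AD filter.

A substitution spec is a scaffold SMILES carrying numbered attachment points
as atom-mapped dummy atoms (``[*:1]``, ``[*:2]`` ...) plus, per site, a list of
named substituent fragments each carrying the matching dummy.  Candidates are
assembled with RDKit's ``molzip``; grafts that violate valence rules are
rejected and logged, never silently dropped.  Each surviving candidate is
predicted with the fitted model and classified against the applicability
domain; the ranking covers in-domain candidates only, but out-of-domain ones
stay in the result table with their flag.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admodel import williams
from .descriptors import DescriptorMatrix, compute_matrix
from .molgraph import MolecularGraph, parse_smiles
from .regression import RegressionModel

__all__ = ["SubstitutionSpec", "ScreeningResult", "enumerate_candidates", "screen", "read_spec_file"]


@dataclass
class SubstitutionSpec:
    scaffold: str  # SMILES with [*:n] attachment points
    sites: dict[int, dict[str, str]]  # site -> {substituent name: fragment SMILES}
    mode: str = "cross-product"  # "cross-product" | "explicit"
    pairs: list[tuple[str, ...]] = field(default_factory=list)  # explicit mode

    def __post_init__(self) -> None:
        found = {int(m) for m in re.findall(r"\[\*:(\d+)\]", self.scaffold)}
        if found != set(self.sites):
            raise ValueError(
                f"scaffold attachment points {sorted(found)} do not match "
                f"site lists {sorted(self.sites)}"
            )
        for site, subs in self.sites.items():
            if not subs:
                raise ValueError(f"empty substituent list at site {site}")
        if self.mode not in ("cross-product", "explicit"):
            raise ValueError("mode must be 'cross-product' or 'explicit'")
        if self.mode == "explicit" and not self.pairs:
            raise ValueError("explicit mode requires a pair list")


def _assemble(scaffold: str, site_fragments: dict[int, str]) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        raise ValueError(f"invalid scaffold SMILES {scaffold!r}")
    for site, frag_smiles in site_fragments.items():
        frag = Chem.MolFromSmiles(frag_smiles)
        if frag is None:
            raise ValueError(f"invalid fragment SMILES {frag_smiles!r} for site {site}")
        mol = Chem.molzip(Chem.CombineMols(mol, frag))
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def enumerate_candidates(
    spec: SubstitutionSpec,
) -> tuple[list[MolecularGraph], list[tuple[str, str]]]:
    """Assemble candidate molecules; returns (graphs, rejection log).

    Candidate ids join the substituent names site-by-site ("Br_Et" for X=Br,
    Y=Et).  Fragments whose graft fails RDKit sanitisation are rejected with
    the reason logged.
    """
    site_ids = sorted(spec.sites)
    if spec.mode == "cross-product":
        combos = list(itertools.product(*(sorted(spec.sites[s]) for s in site_ids)))
    else:
        for tup in spec.pairs:
            if len(tup) != len(site_ids):
                raise ValueError(f"pair {tup} does not cover sites {site_ids}")
        combos = [tuple(tup) for tup in spec.pairs]
    graphs: list[MolecularGraph] = []
    rejects: list[tuple[str, str]] = []
    for combo in combos:
        cid = "_".join(combo)
        frags = {s: spec.sites[s][name] for s, name in zip(site_ids, combo)}
        try:
            smiles = _assemble(spec.scaffold, frags)
            graphs.append(parse_smiles(smiles, id=cid))
        except Exception as exc:  # valence violation or bad fragment
            rejects.append((cid, str(exc)))
    return graphs, rejects


@dataclass
class ScreeningResult:
    table: pd.DataFrame  # candidate_id, smiles, predicted, leverage, in_domain, rank
    h_star: float
    rejects: list[tuple[str, str]]


def screen(
    candidates: list[MolecularGraph],
    model: RegressionModel,
    X_train: DescriptorMatrix,
    y_train,
    smiles: dict[str, str] | None = None,
) -> ScreeningResult:
    """Predict and AD-classify candidates; rank the in-domain ones by potency.

    The candidates' descriptors are computed with the model's descriptor names
    on the raw scale (the same convention the training matrix uses); leverage
    and h* come from the model space of the training set.
    """
    if not candidates:
        raise ValueError("no candidates to screen")
    X_cand = compute_matrix(candidates, model.names)
    ad = williams(model, X_train, y_train, X_cand, y_probe=None)
    tab = ad.table[["predicted", "leverage", "in_domain"]].copy()
    tab.insert(0, "candidate_id", tab.index)
    if smiles:
        tab.insert(1, "smiles", [smiles.get(cid, "") for cid in tab.index])
    order = tab["predicted"].where(tab["in_domain"], -np.inf)
    ranks = order.rank(ascending=False, method="first")
    tab["rank"] = ranks.where(tab["in_domain"]).astype("Int64")
    tab = tab.sort_values(
        by=["in_domain", "predicted"], ascending=[False, False], kind="stable"
    )
    return ScreeningResult(table=tab, h_star=ad.h_star, rejects=[])


def read_spec_file(path) -> SubstitutionSpec:
    """Parse the plain-text spec format: ``[scaffold]``, ``[site N]`` and
    ``[mode]`` sections; one ``name SMILES`` pair per substituent line."""
    scaffold = None
    sites: dict[int, dict[str, str]] = {}
    mode = "cross-product"
    pairs: list[tuple[str, ...]] = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = re.match(r"^\[(.+)\]$", line)
            if m:
                section = m.group(1).strip().lower()
                continue
            if section == "scaffold":
                scaffold = line
            elif section and section.startswith("site"):
                site = int(section.split()[1])
                name, smi = line.split()
                sites.setdefault(site, {})[name] = smi
            elif section == "mode":
                mode = line
            elif section == "pairs":
                pairs.append(tuple(line.split()))
            else:
                raise ValueError(f"line outside a known section: {line!r}")
    if scaffold is None:
        raise ValueError("spec file has no [scaffold] section")
    return SubstitutionSpec(scaffold=scaffold, sites=sites, mode=mode, pairs=pairs)
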