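"""The 881-key substructure dictionary behind :func:`nerd.featurize.compute_fingerprint`.

The fingerprint is a fixed-length binary presence vector over a dictionary of
substructure keys, organized CACTVS-style into sections:

  1. hierarchical element counts ("at least n atoms of element X"),
  2. ring keys (size x composition x aromaticity/saturation x count),
  3. bonded element pairs (any bond order, plus bond-order-specific pairs),
  4. atom neighborhoods (a center element with a multiset of bonded neighbors),
  5. curated functional groups,
  6. element-environment keys (degree, charge, ring membership) filling the
     dictionary to exactly 881 keys.

The dictionary is generated deterministically at import time and its layout is
frozen by construction order; the total length is asserted to be exactly 881.
No installed toolkit exposes the PubChem key set itself, so this dictionary is
this package's own: it preserves the *format* the model consumes (an 881-bit
deterministic substructure vector), not the identity of PubChem's keys.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations_with_replacement

from rdkit import Chem

N_BITS = 881

_ELEMENT_THRESHOLDS = [
    ("H", (4, 8, 16, 32)),
    ("C", (2, 4, 8, 16, 24, 32)),
    ("N", (1, 2, 4, 6, 8)),
    ("O", (1, 2, 4, 8, 12, 16)),
    ("S", (1, 2, 4)),
    ("F", (1, 2, 4, 8)),
    ("Cl", (1, 2, 4)),
    ("Br", (1, 2)),
    ("I", (1, 2)),
    ("P", (1, 2)),
    ("B", (1,)),
    ("Si", (1,)),
    ("Se", (1,)),
]
_METALS = ["Li", "Na", "K", "Mg", "Ca", "Fe", "Zn", "Cu", "Mn", "Co", "Ni",
           "As", "Al", "Sn", "Ag", "Pd", "Pt", "Au", "Hg", "Pb", "Ti", "V",
           "Cr", "Ge"]

_RING_SIZES = range(3, 11)
_RING_PROPS = ["any", "carbon_only", "nitrogen", "oxygen", "hetero",
               "aromatic", "saturated", "unsaturated"]

_PAIR_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si"]
_BOND_SPECIFIC_PAIRS = [
    "C=C", "C#C", "C=N", "C#N", "C=O", "C=S", "N=N", "N=O", "S=O",
    "c:c", "c:n", "c:o", "c:s", "n:n",
]

_NBR2_CENTERS = ["C", "N", "O", "S", "P"]
_NBR2_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br"]
_NBR3_CENTERS = ["C", "N"]

_FUNCTIONAL_GROUPS = [
    ("carboxylic_acid", "C(=O)[OX2H1]"),
    ("carboxylate", "C(=O)[O-]"),
    ("ester", "C(=O)O[#6]"),
    ("amide", "C(=O)[NX3]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("primary_amine", "[NX3;H2;!$(NC=O)][#6]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O)]([#6])[#6]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O)]([#6])([#6])[#6]"),
    ("hydroxyl", "[OX2H][#6]"),
    ("phenol", "[OX2H]c"),
    ("ether", "[OD2]([#6])[#6]"),
    ("aromatic_ether", "[OD2](c)[#6]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SD2]([#6])[#6]"),
    ("disulfide", "[SX2][SX2]"),
    ("nitro", "[NX3](=O)=O"),
    ("nitro_charged", "[NX3+](=O)[O-]"),
    ("nitrile", "C#N"),
    ("isocyanate", "N=C=O"),
    ("azide", "N=[N+]=[N-]"),
    ("azo", "[#6]N=N[#6]"),
    ("imine", "[CX3]=[NX2]"),
    ("oxime", "[CX3]=[NX2][OX2H]"),
    ("hydrazine", "[NX3][NX3]"),
    ("urea", "[NX3]C(=O)[NX3]"),
    ("carbamate", "[NX3]C(=O)O"),
    ("guanidine", "[NX3]C(=[NX2])[NX3]"),
    ("amidine", "C(=[NX2])[NX3]"),
    ("sulfonamide", "S(=O)(=O)[NX3]"),
    ("sulfone", "S(=O)(=O)([#6])[#6]"),
    ("sulfoxide", "[#16X3]=[OX1]"),
    ("sulfonic_acid", "S(=O)(=O)[OX2H]"),
    ("sulfate_ester", "OS(=O)(=O)O"),
    ("phosphate", "P(=O)(O)(O)O"),
    ("phosphonate", "P(=O)(O)O"),
    ("anhydride", "C(=O)OC(=O)"),
    ("acyl_halide", "C(=O)[F,Cl,Br,I]"),
    ("halo_aromatic", "c[F,Cl,Br,I]"),
    ("halo_aliphatic", "[CX4][F,Cl,Br,I]"),
    ("trifluoromethyl", "C(F)(F)F"),
    ("gem_dihalide", "C([F,Cl,Br,I])[F,Cl,Br,I]"),
    ("epoxide", "C1OC1"),
    ("aziridine", "C1NC1"),
    ("lactone", "[C;R](=O)[O;R]"),
    ("lactam", "[C;R](=O)[N;R]"),
    ("aromatic_n", "[nX2]"),
    ("aromatic_nh", "[nH]"),
    ("aromatic_o", "o"),
    ("aromatic_s", "s"),
    ("pyridine_like", "c1ccncc1"),
    ("pyrimidine_like", "c1cncnc1"),
    ("pyrrole_like", "c1cc[nH]c1"),
    ("furan_like", "c1ccoc1"),
    ("thiophene_like", "c1ccsc1"),
    ("imidazole_like", "c1c[nH]cn1"),
    ("benzene", "c1ccccc1"),
    ("naphthalene_like", "c1ccc2ccccc2c1"),
    ("ring_n_sp3", "[NX3;R]"),
    ("ring_o", "[OX2;R]"),
    ("ring_s", "[SX2;R]"),
    ("spiro_carbon", "[CX4](@[*])(@[*])(@[*])@[*]"),
    ("allylic_carbon", "[CX4][CX3]=[CX3]"),
    ("vinyl", "[CX3H2]=[CX3H1]"),
    ("alkyne_terminal", "[CX2H]#C"),
    ("benzylic_carbon", "[CX4]c"),
    ("acetal", "[CX4]([OX2])[OX2]"),
    ("hemiacetal", "[CX4]([OX2H])[OX2][#6]"),
    ("enol_ether", "[CX3]=[CX3][OX2][#6]"),
    ("alpha_beta_unsat_carbonyl", "C=CC=O"),
    ("quaternary_n", "[NX4+]"),
    ("n_oxide", "[NX3+][O-]"),
    ("carbonate", "OC(=O)O"),
    ("thioamide", "C(=S)[NX3]"),
    ("thiourea", "[NX3]C(=S)[NX3]"),
    ("isothiocyanate", "N=C=S"),
    ("sulfonyl_halide", "S(=O)(=O)[F,Cl,Br,I]"),
    ("phosphine", "[PX3]"),
    ("boronic_acid", "B(O)O"),
    ("silyl_ether", "[Si][OX2]"),
    ("peroxide", "[OX2][OX2]"),
    ("methoxy", "[OX2][CH3]"),
    ("n_methyl", "[NX3][CH3]"),
    ("tert_butyl", "C(C)(C)(C)"),
    ("isopropyl", "[CH](C)C"),
    ("long_chain", "CCCCCC"),
    ("dimethylamino", "N(C)C"),
    ("cyano_aromatic", "cC#N"),
    ("amino_aromatic", "c[NX3]"),
]

# padding family: element environments (degree / formal charge / ring membership)
_ENV_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si"]


def _element_smarts(symbol: str) -> str:
    return f"[#{Chem.GetPeriodicTable().GetAtomicNumber(symbol)}]"


def _build_keys() -> list[tuple[str, str, object]]:
    """Return the ordered key list as (name, kind, payload) triples.

    kinds: "element_count" -> (symbol, n); "ring" -> (size, prop, n);
    "smarts" -> compiled-pattern index payload (smarts string).
    """
    keys: list[tuple[str, str, object]] = []

    # section 1: element counts
    for symbol, thresholds in _ELEMENT_THRESHOLDS:
        for n in thresholds:
            keys.append((f"count_{symbol}>={n}", "element_count", (symbol, n)))
    for symbol in _METALS:
        keys.append((f"count_{symbol}>=1", "element_count", (symbol, 1)))

    # section 2: ring keys
    for size in _RING_SIZES:
        for prop in _RING_PROPS:
            for n in (1, 2):
                keys.append((f"ring{size}_{prop}>={n}", "ring", (size, prop, n)))
    for n in (1, 2, 3, 4):
        keys.append((f"aromatic_rings>={n}", "ring", (0, "aromatic", n)))
    for n in (1, 2):
        keys.append((f"hetero_aromatic_rings>={n}", "ring", (0, "hetero_aromatic", n)))
    for n in (1, 2, 3, 4, 5, 6):
        keys.append((f"rings>={n}", "ring", (0, "any", n)))

    # section 3: bonded pairs
    for a, b in combinations_with_replacement(_PAIR_ELEMENTS, 2):
        smarts = f"{_element_smarts(a)}~{_element_smarts(b)}"
        keys.append((f"pair_{a}~{b}", "smarts", smarts))
    for pair in _BOND_SPECIFIC_PAIRS:
        keys.append((f"pair_{pair}", "smarts", pair))

    # section 4: neighborhoods
    for center in _NBR2_CENTERS:
        for nbrs in combinations_with_replacement(_NBR2_ELEMENTS, 2):
            smarts = _element_smarts(center) + "".join(
                f"(~{_element_smarts(x)})" for x in nbrs)
            keys.append((f"nbr_{center}({nbrs[0]})({nbrs[1]})", "smarts", smarts))
    for center in _NBR3_CENTERS:
        for nbrs in combinations_with_replacement(_NBR2_ELEMENTS, 3):
            smarts = _element_smarts(center) + "".join(
                f"(~{_element_smarts(x)})" for x in nbrs)
            keys.append((f"nbr_{center}" + "".join(f"({x})" for x in nbrs),
                         "smarts", smarts))

    # section 5: functional groups
    for name, smarts in _FUNCTIONAL_GROUPS:
        keys.append((f"fg_{name}", "smarts", smarts))

    # section 6: element environments, sliced to pad the total to exactly 881
    env: list[tuple[str, str, object]] = []
    pt = Chem.GetPeriodicTable()
    for symbol in _ENV_ELEMENTS:
        num = pt.GetAtomicNumber(symbol)
        for degree in (1, 2, 3, 4):
            env.append((f"env_{symbol}_D{degree}", "smarts", f"[#{num};D{degree}]"))
        env.append((f"env_{symbol}_ring", "smarts", f"[#{num};R]"))
        env.append((f"env_{symbol}_chain", "smarts", f"[#{num};!R]"))
        for charge, tag in ((1, "pos"), (-1, "neg")):
            env.append((f"env_{symbol}_{tag}", "smarts",
                        f"[#{num};{'+' if charge > 0 else '-'}]"))
        for h in (0, 1, 2, 3):
            env.append((f"env_{symbol}_H{h}", "smarts", f"[#{num};H{h}]"))
    remainder = N_BITS - len(keys)
    if remainder < 0:
        raise AssertionError(f"key dictionary overflows 881 ({len(keys)} base keys)")
    if remainder > len(env):
        raise AssertionError(
            f"padding family too small: need {remainder}, have {len(env)}")
    keys.extend(env[:remainder])
    assert len(keys) == N_BITS
    return keys


KEYS = _build_keys()


@lru_cache(maxsize=None)
def _compiled(smarts: str):
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:  # pragma: no cover - layout is fixed
        raise ValueError(f"invalid SMARTS in key dictionary: {smarts}")
    return patt


def _ring_flags(mol) -> list[dict]:
    rings = []
    for atom_ids in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in atom_ids]
        symbols = {a.GetSymbol() for a in atoms}
        aromatic = all(a.GetIsAromatic() for a in atoms)
        bonds = []
        n = len(atom_ids)
        for i in range(n):
            bonds.append(mol.GetBondBetweenAtoms(atom_ids[i], atom_ids[(i + 1) % n]))
        saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        rings.append({
            "size": n,
            "aromatic": aromatic,
            "carbon_only": symbols == {"C"},
            "nitrogen": "N" in symbols,
            "oxygen": "O" in symbols,
            "hetero": bool(symbols - {"C"}),
            "saturated": saturated,
            "unsaturated": (not saturated) and (not aromatic),
            "hetero_aromatic": aromatic and bool(symbols - {"C"}),
            "any": True,
        })
    return rings


def evaluate_keys(mol) -> "list[int]":
    """Evaluate all 881 keys on an RDKit molecule; returns 0/1 ints in order."""
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
    rings = _ring_flags(mol)

    bits = []
    for _name, kind, payload in KEYS:
        if kind == "element_count":
            symbol, n = payload
            bits.append(1 if counts.get(symbol, 0) >= n else 0)
        elif kind == "ring":
            size, prop, n = payload
            matching = [r for r in rings
                        if (size == 0 or r["size"] == size) and r[prop]]
            bits.append(1 if len(matching) >= n else 0)
        else:
            bits.append(1 if mol.HasSubstructMatch(_compiled(payload)) else 0)
    return bits
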