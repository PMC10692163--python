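"""Packaged synthon fragment lists for the synthetic combinatorial library.

Three fragment sets mimic a make-on-demand amide-coupling space built largely
from amino-acid-like building blocks:

* ``ACYL`` — carboxylic-acid components, written as ``O=C(R)`` SMILES prefixes
  whose carbonyl carbon accepts the next written atom (the amide nitrogen).
* ``AMINO`` — central alpha-amino-acid cores, written as ``NC(S)C(=O)``; the
  leading nitrogen couples to an acyl fragment and the trailing carbonyl is
  terminated either as a free acid (A–B products) or a second amide (A–B–C).
* ``AMINE`` — amine caps, written with the nitrogen first so they terminate
  an A–B–C product as a C-terminal amide.

Each set holds exactly 100 fragments spread over many distinct ring systems,
linkers and decorations, so that products sharing no fragment are
structurally dissimilar — matching the scaffold diversity of the
billion-scale make-on-demand spaces the library stands in for.  The
enumerable product space (100·100 two-component + 100³ three-component
couplings) exceeds one million unique molecules.

Fragments are assembled by plain string concatenation; every product parses
because each fragment is a valid SMILES continuation and all ring-bond
numbers close within their fragment.
"""

from __future__ import annotations

# acyl substituents R in O=C(R)-: six- and five-membered (hetero)aromatics,
# CH2-linked aromatics, saturated rings (C-, N- and CH2-linked) and acyclic
# polar/lipophilic groups, one characteristic decoration each
_ACYL_R: list[str] = [
    "c1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(C)cc1", "c1ccc(OC)cc1",
    "c1ccc(O)cc1", "c1ccc(C#N)cc1", "c1cccc(F)c1", "c1cccc(OC)c1", "c1ccc(F)c(F)c1",
    "c1ccncc1", "c1cccnc1", "c1ccccn1", "c1cc(C)ncc1", "c1cc(OC)ncc1",
    "c1cncnc1", "c1cnccn1", "c1ccnnc1", "c1cc(F)cnc1", "c1ncccn1",
    "c1ccco1", "c1cccs1", "c1cc[nH]c1", "c1ccn(C)c1", "c1cnc[nH]1",
    "c1cnn(C)c1", "c1cscn1", "c1cocn1", "c1conc1", "c1csnc1",
    "c1oc(C)cc1", "c1sc(C)cc1", "c1nc(C)sc1", "c1nc(C)oc1", "c1cn(C)nc1",
    "Cc1ccccc1", "Cc1ccc(F)cc1", "Cc1ccc(OC)cc1", "Cc1ccncc1", "Cc1cccnc1",
    "Cc1ccccn1", "Cc1cncnc1", "Cc1cnccn1", "Cc1ccco1", "Cc1cccs1",
    "Cc1cnc[nH]1", "Cc1cnn(C)c1", "Cc1conc1", "Cc1cscn1", "COc1ccccc1",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1COC1",
    "C1CCOC1", "C1CCOCC1", "C1CN(C)C1", "C1CCN(C)C1", "C1CCN(C)CC1",
    "C1CCS(=O)(=O)CC1", "C1CCC(F)(F)CC1", "C1CCC(C)CC1", "C1CCC(O)CC1", "C1CCC(OC)CC1",
    "N1CCC1", "N1CCCC1", "N1CCCCC1", "N1CCOCC1", "N1CCN(C)CC1",
    "N1CCS(=O)(=O)CC1", "N1CCC(C)CC1", "N1CCC(O)CC1", "N1CCC(F)(F)CC1", "CC1CC1",
    "CC1CCC1", "CC1CCCCC1", "CC1CCOC1", "CC1CCOCC1", "CN1CCOCC1",
    "CN1CCCC1", "CC1CCN(C)C1", "CC1CCS(=O)(=O)C1", "C", "CC",
    "CCC", "C(C)C", "CC(C)C", "COC", "CC#N",
    "C(F)(F)F", "CCO", "CN(C)C", "CS(C)(=O)=O", "CCS(C)(=O)=O",
    "CC(=O)O", "CCC(=O)O", "CC(=O)NC", "CC(=O)N(C)C", "CCN(C)C",
]

# alpha side chains S in -NC(S)C(=O)-: proteinogenic-like chains first, then
# CH2-linked (hetero)aromatics, saturated rings and polar chains
_AMINO_S: list[str] = [
    "", "C", "CC", "C(C)C", "CC(C)C",
    "C(C)CC", "C(C)O", "CO", "CS", "CCSC",
    "CC(=O)O", "CCC(=O)O", "CC(N)=O", "CCC(N)=O", "Cc1ccc(O)cc1",
    "Cc1c[nH]cn1", "Cc1c[nH]c2ccccc12", "CCO", "CCC", "Cc1ccccc1",
    "Cc1ccc(F)cc1", "Cc1ccc(Cl)cc1", "Cc1ccc(C)cc1", "Cc1ccc(OC)cc1", "Cc1ccc(C#N)cc1",
    "Cc1cccc(F)c1", "Cc1cccc(OC)c1", "Cc1ccc(S(C)(=O)=O)cc1", "Cc1ccc(S(N)(=O)=O)cc1", "Cc1ccncc1",
    "Cc1cccnc1", "Cc1ccccn1", "Cc1cncnc1", "Cc1cnccn1", "Cc1ccnnc1",
    "Cc1ccco1", "Cc1cccs1", "Cc1ccn(C)c1", "Cc1cnn(C)c1", "Cc1conc1",
    "Cc1csnc1", "Cc1cscn1", "Cc1cocn1", "Cc1cnc[nH]1", "Cc1oc(C)cc1",
    "Cc1sc(C)cc1", "Cc1nc(C)sc1", "Cc1cn(C)nc1", "COc1ccccc1", "C1CC1",
    "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCOCC1", "C1COC1",
    "CC1CC1", "CC1CCC1", "CC1CCCC1", "CC1CCCCC1", "CC1CCOC1",
    "CC1CCOCC1", "CC1CCN(C)C1", "CN1CCOCC1", "CN1CCCC1", "CC1CCS(=O)(=O)C1",
    "C1CCN(C)CC1", "CC1CCN(C)CC1", "CCCO", "COC", "CCOC",
    "COCC", "CC(C)O", "CC(F)(F)F", "CC#N", "CCN(C)C",
    "CCS(C)(=O)=O", "CS(C)(=O)=O", "CC(=O)NC", "CCC(=O)NC", "CC(=O)N(C)C",
    "CC(C)(C)O", "CCC#N", "CCCOC", "Cc1ccc(O)c(F)c1", "Cc1ccc(F)c(F)c1",
    "Cc1cc(F)cc(F)c1", "Cc1ccc(OC)c(O)c1", "Cc1cnc(C)cn1", "CCc1ccncc1", "CCc1ccco1",
    "CCc1cccs1", "CCc1cnccn1", "Cc1cc(C)on1", "Cc1cc(C)ns1", "Cc1nnc(C)s1",
    "Cc1nnc(C)o1", "Cc1cn(C)cn1", "Cc1cc2ccccc2o1", "Cc1cc2ccccc2[nH]1", "Cc1ccc(N(C)C)cc1",
]

# amine caps, nitrogen written first: acyclic and cyclic amines, ring-C
# attached amines, benzylic/heteroarylmethyl amines and anilines
_AMINE: list[str] = [
    "NC", "NCC", "NCCC", "NC(C)C", "NCC(C)C",
    "NCCO", "NCCOC", "NCC(F)(F)F", "NCC#N", "N(C)C",
    "N(C)CC", "N(CC)CC", "N(C)CCO", "NCC(C)O", "NCCCOC",
    "NCCN(C)C", "NCCS(C)(=O)=O", "NCCCN(C)C", "NCCOCC", "NC(C)CC",
    "N1CCC1", "N1CCCC1", "N1CCCCC1", "N1CCOCC1", "N1CCN(C)CC1",
    "N1CCS(=O)(=O)CC1", "N1CCC(C)CC1", "N1CCC(O)CC1", "N1CCC(OC)CC1", "N1CCC(F)(F)CC1",
    "NC1CC1", "NC1CCC1", "NC1CCCC1", "NC1CCCCC1", "NC1CCOCC1",
    "NCC1CC1", "NCC1CCC1", "NCC1CCCC1", "NCC1CCCCC1", "NCC1CCOCC1",
    "NCC1CCOC1", "NC1COC1", "NCC1COC1", "N(C)C1CCCCC1", "N(C)C1CCCC1",
    "NCc1ccccc1", "NCc1ccc(F)cc1", "NCc1ccc(Cl)cc1", "NCc1ccc(C)cc1", "NCc1ccc(OC)cc1",
    "NCc1ccc(O)cc1", "NCc1ccc(C#N)cc1", "NCc1cccc(F)c1", "NCc1cccc(OC)c1", "NCc1ccc(F)c(F)c1",
    "NCc1ccncc1", "NCc1cccnc1", "NCc1ccccn1", "NCc1cncnc1", "NCc1cnccn1",
    "NCc1ccnnc1", "NCc1ccco1", "NCc1cccs1", "NCc1cc[nH]c1", "NCc1ccn(C)c1",
    "NCc1cnc[nH]1", "NCc1cnn(C)c1", "NCc1conc1", "NCc1csnc1", "NCc1cscn1",
    "NCc1cocn1", "NCc1oc(C)cc1", "NCc1sc(C)cc1", "NCc1nc(C)sc1", "NCc1cn(C)nc1",
    "Nc1ccccc1", "Nc1ccc(F)cc1", "Nc1ccc(C)cc1", "Nc1ccc(OC)cc1", "Nc1ccc(O)cc1",
    "Nc1ccncc1", "Nc1cccnc1", "Nc1cncnc1", "Nc1ccc(C#N)cc1", "Nc1cccc(F)c1",
    "NCCc1ccccc1", "NCCc1ccncc1", "NCCc1ccco1", "NCCc1cccs1", "NCCc1cnccn1",
    "NCc1ccc(S(C)(=O)=O)cc1", "NCc1ccc(S(N)(=O)=O)cc1", "N(C)Cc1ccccc1", "N(C)c1ccccc1", "NCc1ccc(N(C)C)cc1",
    "NC(C)c1ccccc1", "NCCc1ccccn1", "N1CCC(CO)CC1", "NCC(F)F", "N(C)Cc1ccncc1",
]


def acyl_fragments() -> list[str]:
    """Acyl components as ``O=C(R)`` SMILES prefixes (set A)."""
    return [f"O=C({r})" for r in _ACYL_R]


def amino_fragments() -> list[str]:
    """Alpha-amino-acid cores as ``NC(S)C(=O)`` SMILES infixes (set B)."""
    out = []
    for s in _AMINO_S:
        out.append("NCC(=O)" if s == "" else f"NC({s})C(=O)")
    return out


def amine_fragments() -> list[str]:
    """Amine caps as nitrogen-first SMILES suffixes (set C)."""
    return list(_AMINE)


def default_synthon_sets() -> tuple[list[str], list[str], list[str]]:
    """The packaged (acyl, amino, amine) fragment lists, 100 each."""
    a, b, c = acyl_fragments(), amino_fragments(), amine_fragments()
    assert len(a) == len(b) == len(c) == 100, (len(a), len(b), len(c))
    return a, b, c
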