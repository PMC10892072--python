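"""A bundled pool of 150 valid SMILES strings for synthetic datasets.

The pool mixes common cosmetic-relevant molecules (fragrance aldehydes,
preservatives, solvents, known sensitizers such as cinnamaldehyde,
isoeugenol and formaldehyde) with homologous series, so generated tables
carry plausible, syntactically valid structures without any chemistry
dependency. The strings are inputs to the deterministic embedding
fallback; no chemical realism beyond validity is intended.
"""

_NAMED = [
    "C=O",  # formaldehyde
    "CC=O",  # acetaldehyde
    "O=C/C=C/c1ccccc1",  # cinnamaldehyde
    "COc1cc(/C=C/C)ccc1O",  # isoeugenol
    "COc1cc(CC=C)ccc1O",  # eugenol
    "CC(C)=CCCC(C)CCO",  # citronellol
    "CC(C)=CCC/C(C)=C/CO",  # geraniol
    "O=CCCCCCCCC=O",  # azelaaldehyde-like dial
    "Oc1ccccc1",  # phenol
    "Nc1ccccc1",  # aniline
    "Cc1ccccc1",  # toluene
    "c1ccccc1",  # benzene
    "O=Cc1ccccc1",  # benzaldehyde
    "OCc1ccccc1",  # benzyl alcohol
    "CC(=O)OCc1ccccc1",  # benzyl acetate
    "O=C(O)c1ccccc1",  # benzoic acid
    "OC(=O)/C=C/c1ccccc1",  # cinnamic acid
    "COC(=O)c1ccccc1",  # methyl benzoate
    "CCOC(=O)c1ccccc1",  # ethyl benzoate
    "Oc1ccc(O)cc1",  # hydroquinone
    "Oc1ccccc1O",  # catechol
    "Oc1cccc(O)c1",  # resorcinol
    "Nc1ccc(N)cc1",  # p-phenylenediamine
    "Nc1ccc(O)cc1",  # p-aminophenol
    "O=[N+]([O-])c1ccccc1",  # nitrobenzene
    "Clc1ccccc1",  # chlorobenzene
    "Clc1ccc(Cl)cc1",  # dichlorobenzene
    "BrCCCCCC",  # hexyl bromide
    "ClCC=C",  # allyl chloride
    "C=CCOC(=O)C",  # allyl acetate
    "O=C1CCCCC1",  # cyclohexanone
    "OC1CCCCC1",  # cyclohexanol
    "C1CCCCC1",  # cyclohexane
    "C1CCOC1",  # THF
    "C1COCCO1",  # dioxane
    "CC(C)O",  # isopropanol
    "CC(C)=O",  # acetone
    "CC(=O)O",  # acetic acid
    "OCC(O)CO",  # glycerol
    "OCCO",  # ethylene glycol
    "CCOCC",  # diethyl ether
    "CC(=O)CC(C)C",  # MIBK-like
    "CSC",  # dimethyl sulfide
    "CS(=O)C",  # DMSO
    "NC(=O)N",  # urea
    "NCCS",  # cysteamine
    "NCC(=O)O",  # glycine
    "NC(CS)C(=O)O",  # cysteine
    "NCCCCC(N)C(=O)O",  # lysine
    "OC(=O)CCC(=O)O",  # succinic acid
    "OC(=O)/C=C/C(=O)O",  # fumaric acid
    "OC(=O)C(O)C(O)C(=O)O",  # tartaric acid
    "CC(O)C(=O)O",  # lactic acid
    "O=C(C)Oc1ccccc1C(=O)O",  # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(=O)Nc1ccc(O)cc1",  # paracetamol
    "CC12CCC(CC1)C(C)(C)O2",  # eucalyptol
    "CC1=CCC(CC1)C(C)C",  # terpinene-like
    "CC(C)c1ccc(C)cc1",  # p-cymene
    "CC1=CCC(CC1)C(C)(C)O",  # terpineol
    "CC(C)(C)c1ccc(O)cc1",  # 4-tert-butylphenol
    "COc1ccc(C=O)cc1",  # anisaldehyde
    "COc1ccccc1",  # anisole
    "CCc1ccccc1",  # ethylbenzene
    "C=Cc1ccccc1",  # styrene
    "OO",  # hydrogen peroxide
    "ClC(Cl)(Cl)Cl",  # carbon tetrachloride
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccc2c(c1)ccc1ccccc12",  # phenanthrene
    "c1ccncc1",  # pyridine
    "c1ccc(nc1)N",  # 2-aminopyridine
    "c1cc[nH]c1",  # pyrrole
    "c1ccoc1",  # furan
    "c1ccsc1",  # thiophene
    "O=C1OC(=O)c2ccccc21",  # phthalic anhydride
    "C(=O)(O)c1ccccc1O",  # salicylic acid
    "CCCCCCCCCCCCOS(=O)(=O)O",  # lauryl sulfate
    "CCCCCCCC/C=C\\CCCCCCCC(=O)O",  # oleic acid
    "CCOC(=O)C",  # ethyl acetate
    "CC(C)CO",  # isobutanol
]

# homologous series pad the pool to a fixed size of 150
_ALKANES = ["C" * n for n in range(1, 16)]
_ALCOHOLS = ["C" * n + "O" for n in range(2, 16)]
_ACIDS = ["C" * n + "C(=O)O" for n in range(1, 13)]
_AMINES = ["C" * n + "N" for n in range(1, 13)]
_ESTERS = ["COC(=O)" + "C" * n for n in range(1, 11)]
_ALDEHYDES = ["C" * n + "C=O" for n in range(2, 10)]

SMILES_POOL: tuple[str, ...] = tuple(
    dict.fromkeys(_NAMED + _ALKANES + _ALCOHOLS + _ACIDS + _AMINES + _ESTERS + _ALDEHYDES)
)[:150]

assert len(SMILES_POOL) == 150
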