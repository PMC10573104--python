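# Synthetic CSG residue template.
#
# SYNTHETIC STAND-IN: ff14SB cysteine backbone charges combined with
# chemically standard internal coordinates for the glutathione moiety;
# side-chain charges are plausible amide/carboxylate/amine values
# normalized to a total residue charge of -1 by the package's own
# normalization procedure.  Replace with a fitted library for
# production parameterization work.

[template]
name = "CSG"
head = "N"
tail = "C"
atoms = [
    ["N", "N", -0.415700],
    ["H", "H", 0.271900],
    ["CA", "CX", 0.021300],
    ["HA", "H1", 0.112400],
    ["CB", "2C", -0.080585],
    ["HB2", "H1", 0.089415],
    ["HB3", "H1", 0.089415],
    ["SG", "S", -0.109670],
    ["C", "C", 0.597300],
    ["O", "O", -0.567900],
    ["SG2", "S", -0.109685],
    ["CB2", "2C", -0.080585],
    ["HB21", "H1", 0.089415],
    ["HB22", "H1", 0.089415],
    ["CA2", "CX", 0.019715],
    ["HA2", "H1", 0.110815],
    ["N2", "N", -0.417285],
    ["H2", "H", 0.270315],
    ["CD1", "C", 0.595715],
    ["OE1", "O", -0.569485],
    ["CG1", "2C", -0.041385],
    ["HG11", "HC", 0.041415],
    ["HG12", "HC", 0.041415],
    ["CB1", "2C", -0.031685],
    ["HB11", "HC", 0.041415],
    ["HB12", "HC", 0.041415],
    ["CA1", "CX", 0.094615],
    ["HA1", "HP", 0.087315],
    ["N1", "N3", -0.383685],
    ["H11", "H", 0.283415],
    ["H12", "H", 0.283415],
    ["H13", "H", 0.283415],
    ["C1", "CO", 0.797815],
    ["O11", "O2", -0.802985],
    ["O12", "O2", -0.802985],
    ["C2", "C", 0.595715],
    ["O2", "O", -0.569485],
    ["N3", "N", -0.417285],
    ["H4", "H", 0.270315],
    ["CA3", "CX", -0.150585],
    ["HA31", "H1", 0.087415],
    ["HA32", "H1", 0.087415],
    ["C3", "CO", 0.771515],
    ["O31", "O2", -0.807085],
    ["O32", "O2", -0.807085],
]
bonds = [
    ["N", "H"],
    ["N", "CA"],
    ["CA", "HA"],
    ["CA", "CB"],
    ["CA", "C"],
    ["C", "O"],
    ["CB", "HB2"],
    ["CB", "HB3"],
    ["CB", "SG"],
    ["SG", "SG2"],
    ["SG2", "CB2"],
    ["CB2", "HB21"],
    ["CB2", "HB22"],
    ["CB2", "CA2"],
    ["CA2", "HA2"],
    ["CA2", "N2"],
    ["CA2", "C2"],
    ["N2", "H2"],
    ["N2", "CD1"],
    ["CD1", "OE1"],
    ["CD1", "CG1"],
    ["CG1", "HG11"],
    ["CG1", "HG12"],
    ["CG1", "CB1"],
    ["CB1", "HB11"],
    ["CB1", "HB12"],
    ["CB1", "CA1"],
    ["CA1", "HA1"],
    ["CA1", "N1"],
    ["CA1", "C1"],
    ["N1", "H11"],
    ["N1", "H12"],
    ["N1", "H13"],
    ["C1", "O11"],
    ["C1", "O12"],
    ["C2", "O2"],
    ["C2", "N3"],
    ["N3", "H4"],
    ["N3", "CA3"],
    ["CA3", "HA31"],
    ["CA3", "HA32"],
    ["CA3", "C3"],
    ["C3", "O31"],
    ["C3", "O32"],
]
zmatrix = [
    ["SG2", "SG", "CB", "CA", 2.04, 104.0, 180.0],
    ["CB2", "SG2", "SG", "CB", 1.81, 104.0, 90.0],
    ["CA2", "CB2", "SG2", "SG", 1.53, 112.0, 180.0],
    ["HB21", "CB2", "SG2", "SG", 1.09, 109.0, 59.0],
    ["HB22", "CB2", "SG2", "SG", 1.09, 109.0, -59.0],
    ["N2", "CA2", "CB2", "SG2", 1.46, 110.0, -65.0],
    ["C2", "CA2", "CB2", "SG2", 1.53, 111.0, 175.0],
    ["HA2", "CA2", "CB2", "SG2", 1.09, 108.0, 55.0],
    ["N3", "C2", "CA2", "N2", 1.33, 114.5, 160.0],
    ["O2", "C2", "N3", "CA2", 1.23, 123.0, 180.0],
    ["H4", "N3", "C2", "CA2", 1.01, 119.0, 0.0],
    ["CA3", "N3", "C2", "CA2", 1.45, 121.0, 180.0],
    ["HA31", "CA3", "N3", "C2", 1.09, 109.0, 60.0],
    ["HA32", "CA3", "N3", "C2", 1.09, 109.0, -60.0],
    ["C3", "CA3", "N3", "C2", 1.52, 111.0, 180.0],
    ["O31", "C3", "CA3", "N3", 1.25, 117.0, 0.0],
    ["O32", "C3", "CA3", "N3", 1.25, 117.0, 180.0],
    ["CD1", "N2", "CA2", "CB2", 1.33, 121.0, 150.0],
    ["H2", "N2", "CD1", "CA2", 1.01, 118.0, 180.0],
    ["OE1", "CD1", "N2", "CA2", 1.23, 123.0, 0.0],
    ["CG1", "CD1", "N2", "CA2", 1.51, 116.0, 180.0],
    ["CB1", "CG1", "CD1", "N2", 1.53, 112.0, 180.0],
    ["HG11", "CG1", "CD1", "CB1", 1.09, 108.0, 121.0],
    ["HG12", "CG1", "CD1", "CB1", 1.09, 108.0, -121.0],
    ["CA1", "CB1", "CG1", "CD1", 1.53, 112.0, 180.0],
    ["HB11", "CB1", "CG1", "CA1", 1.09, 108.0, 121.0],
    ["HB12", "CB1", "CG1", "CA1", 1.09, 108.0, -121.0],
    ["N1", "CA1", "CB1", "CG1", 1.49, 110.5, -65.0],
    ["C1", "CA1", "CB1", "CG1", 1.53, 110.5, 175.0],
    ["HA1", "CA1", "CB1", "CG1", 1.09, 108.0, 55.0],
    ["H11", "N1", "CA1", "CB1", 1.01, 109.5, 60.0],
    ["H12", "N1", "CA1", "CB1", 1.01, 109.5, 180.0],
    ["H13", "N1", "CA1", "CB1", 1.01, 109.5, -60.0],
    ["O11", "C1", "CA1", "N1", 1.25, 117.0, -30.0],
    ["O12", "C1", "CA1", "N1", 1.25, 117.0, 150.0],
]
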