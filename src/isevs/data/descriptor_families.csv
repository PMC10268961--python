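descriptor_name,family
MaxPartialCharge,partial_charge
MinPartialCharge,partial_charge
MaxAbsPartialCharge,partial_charge
MinAbsPartialCharge,partial_charge
PEOE_VSA1,partial_charge
PEOE_VSA2,partial_charge
PEOE_VSA3,partial_charge
PEOE_VSA4,partial_charge
PEOE_VSA5,partial_charge
PEOE_VSA6,partial_charge
PEOE_VSA7,partial_charge
PEOE_VSA8,partial_charge
PEOE_VSA9,partial_charge
PEOE_VSA10,partial_charge
PEOE_VSA11,partial_charge
PEOE_VSA12,partial_charge
PEOE_VSA13,partial_charge
PEOE_VSA14,partial_charge
HeavyAtomCount,atom_bond_counts
NHOHCount,atom_bond_counts
NOCount,atom_bond_counts
NumRotatableBonds,atom_bond_counts
RingCount,atom_bond_counts
NumAromaticRings,atom_bond_counts
NumAliphaticRings,atom_bond_counts
NumSaturatedRings,atom_bond_counts
FractionCSP3,atom_bond_counts
NumHeteroatoms,atom_bond_counts
phf_acceptor,pharmacophore_feature
phf_donor,pharmacophore_feature
phf_basic,pharmacophore_feature
phf_acidic,pharmacophore_feature
phf_aromatic_atom,pharmacophore_feature
phf_hydrophobe,pharmacophore_feature
MolWt,physical_properties
MolLogP,physical_properties
NumHAcceptors,physical_properties
NumHDonors,physical_properties
TPSA,physical_properties
MolMR,physical_properties
LabuteASA,physical_properties
SlogP_VSA1,subdivided_surface_areas
SlogP_VSA2,subdivided_surface_areas
SlogP_VSA3,subdivided_surface_areas
SlogP_VSA4,subdivided_surface_areas
SlogP_VSA5,subdivided_surface_areas
SlogP_VSA6,subdivided_surface_areas
SlogP_VSA7,subdivided_surface_areas
SlogP_VSA8,subdivided_surface_areas
SlogP_VSA9,subdivided_surface_areas
SlogP_VSA10,subdivided_surface_areas
SlogP_VSA11,subdivided_surface_areas
SlogP_VSA12,subdivided_surface_areas
SMR_VSA1,subdivided_surface_areas
SMR_VSA2,subdivided_surface_areas
SMR_VSA3,subdivided_surface_areas
SMR_VSA4,subdivided_surface_areas
SMR_VSA5,subdivided_surface_areas
SMR_VSA6,subdivided_surface_areas
SMR_VSA7,subdivided_surface_areas
SMR_VSA8,subdivided_surface_areas
SMR_VSA9,subdivided_surface_areas
SMR_VSA10,subdivided_surface_areas
BalabanJ,adjacency_distance_matrix
BertzCT,adjacency_distance_matrix
Chi0,kier_hall_connectivity
Chi1,kier_hall_connectivity
Chi0v,kier_hall_connectivity
Chi1v,kier_hall_connectivity
Chi2v,kier_hall_connectivity
Chi3v,kier_hall_connectivity
Chi4v,kier_hall_connectivity
Chi0n,kier_hall_connectivity
Chi1n,kier_hall_connectivity
Chi2n,kier_hall_connectivity
Chi3n,kier_hall_connectivity
Chi4n,kier_hall_connectivity
Kappa1,kier_hall_connectivity
Kappa2,kier_hall_connectivity
Kappa3,kier_hall_connectivity
HallKierAlpha,kier_hall_connectivity
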