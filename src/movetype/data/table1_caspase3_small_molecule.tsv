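# caspase-3 / small-molecule inhibitor benchmark (source tag: table1)
# experimental and movable-type-calculated binding free energies, kcal/mol
# printed summary statistics for this set: RMSE 1.242, r^2 0.501, tau 0.357
# recomputation from these rows: RMSE 1.242 and tau 0.357 (=10/28) reproduce
# exactly; r^2 recomputes to 0.492 (within rounding drift of the printed value)
pdb_id	ligand	ligand_mass_da	experimental_dg	calculated_dg
3h0e		455.57	-11.11	-9.15
1gfw		400.45	-10.66	-10.34
3dei		366.32	-10.08	-8.56
3dej		400.77	-10.90	-8.46
3dek		427.38	-10.32	-10.37
1nms		464.45	-9.13	-9.46
1re1		301.09	-7.099	-7.133
1rhm		301.09	-7.849	-7.728
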