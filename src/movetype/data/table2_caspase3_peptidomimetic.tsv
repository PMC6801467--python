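# caspase-3 / peptidomimetic inhibitor benchmark (source tag: table2)
# experimental and movable-type-calculated binding free energies, kcal/mol
# printed summary statistics for this set: RMSE 0.479, r^2 0.655, tau 0.444
# recomputation from these rows: RMSE 0.479 reproduces exactly; r^2 recomputes
# to 0.677 and tau to 0.357 -- both beyond two-decimal rounding of the printed
# values, so the printed correlations are annotations here, not targets
pdb_id	ligand	ligand_mass_da	experimental_dg	calculated_dg
1rhu	5,6,7 tricyclic peptidomimetic	638.69	-11.61	-10.88
1rhr	Cinnamic acid methyl ester	651.14	-11.04	-10.79
1rhj	Pryazinone	574.69	-10.96	-11.02
4jje	ACE-1MH-ASP-B3L-HLX-1U8	838.94	-10.41	-10.90
2h5i	Ac-DEVD-Cho	504.49	-12.11	-11.18
2h5j	Ac-DMQD-Cho	535.57	-10.779	-11.06
4jr0	Ac-DEVD-CMK	552.96	-11.17	-11.26
3gjt	Ac-IEPD	498.13	-9.23	-9.44
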