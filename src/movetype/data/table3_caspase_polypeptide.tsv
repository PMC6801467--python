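# caspase family / polypeptide inhibitor benchmark (source tag: table3)
# experimental and movable-type-calculated binding free energies, kcal/mol
# printed summary statistics for this set: RMSE 0.733, r^2 0.752, tau 0.651
# recomputation from these rows: RMSE 0.733 reproduces exactly; r^2 recomputes
# to 0.748 and tau to 0.657 (within rounding drift of the printed values)
pdb_id	target	ligand	experimental_dg	calculated_dg
2h5j	caspase-3	Ac-DMQD-Cho	-10.78	-11.06
2ql5	caspase-7	Ac-DMQD-Cho	-11.04	-12.72
2ql9	caspase-7	Ac-DQMD-Cho	-12.30	-12.51
2qlf	caspase-7	Ac-DNLD-Cho	-12.06	-12.26
2qlb	caspase-7	Ac-EMSD-Cho	-8.03	-8.46
2ql7	caspase-7	Ac-IEPD-Cho	-8.53	-8.16
1f1j	caspase-7	Ac-DEVD-Cho	-11.99	-10.74
2h5i	caspase-3	Ac-DEVD-Cho	-12.11	-11.18
4jr0	caspase-3	Ac-DEVD-CMK	-11.17	-11.26
3r7b	caspase-2	Ac-DVAD-Cho	-8.38	-8.42
3r5j	caspase-2	Ac-ADVAD-Cho	-9.48	-9.72
3r6g	caspase-2	Ac-VDVAD-Cho	-10.36	-10.68
3gjt	caspase-3	Ac-IEPD	-9.23	-9.44
1f9e	caspase-8	Phq-DEVD	-11.86	-10.49
4jje	caspase-3	Ac-1MH-ASP-B3L-HLX-1U8	-10.41	-10.90
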