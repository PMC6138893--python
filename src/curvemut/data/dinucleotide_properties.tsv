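# Default dinucleotide property table (17 properties x 16 dinucleotides).
# Provenance: assembled from published dinucleotide property compilations:
#   - duplex_free_energy / duplex_enthalpy / duplex_entropy: unified
#     nearest-neighbour DNA duplex thermodynamics (SantaLucia 1998 PNAS),
#     kcal/mol, kcal/mol, cal/(mol K) at 37 C.
#   - twist / roll / tilt / slide / shift / rise: representative base-step
#     geometry from crystallographic compilations (degrees / angstrom).
#   - propeller_twist: per-step propeller twist compilation (degrees).
#   - stacking_energy: base-stacking energies (Ornstein et al. 1978), kcal/mol.
#   - melting_temperature: dinucleotide melting-temperature scale (C).
#   - curvature: wedge-angle-magnitude composite per step (degrees); the
#     helical-axis deflection attributed to each dinucleotide step.
#   - bendability, bending_stiffness, protein_deformability,
#     minor_groove_width: DNase-I bendability propensity, bending force
#     constant, protein-induced deformability, and groove-geometry scales
#     from published compilations (arbitrary/angstrom units).
# Physically strand-symmetric scales satisfy v(d) == v(revcomp(d)); signed
# step parameters (tilt, shift) are antisymmetric under reverse complement.
property	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
curvature	7.2	1.1	1.8	2.6	3.5	2.1	6.7	1.8	5.3	5.0	2.1	1.1	0.9	5.3	3.5	7.2
tilt	-1.4	-0.1	-1.7	0.0	0.5	-0.1	0.0	1.7	-1.5	0.0	0.1	0.1	0.0	1.5	-0.5	1.4
roll	0.3	0.8	4.5	1.1	4.7	3.6	5.4	4.5	1.9	0.3	3.6	0.8	3.3	1.9	4.7	0.3
twist	35.62	34.4	27.7	31.5	34.5	33.67	29.8	27.7	36.9	40.0	33.67	34.4	36.0	36.9	34.5	35.62
slide	-0.08	-0.58	-0.25	-0.59	0.53	-0.22	0.41	-0.25	0.09	-0.38	-0.22	-0.58	0.05	0.09	0.53	-0.08
shift	-0.03	0.13	0.09	0.0	0.09	0.05	0.0	-0.09	-0.28	0.0	-0.05	-0.13	0.0	0.28	-0.09	0.03
rise	3.27	3.36	3.34	3.31	3.33	3.42	3.39	3.34	3.37	3.40	3.42	3.36	3.42	3.37	3.33	3.27
propeller_twist	-18.66	-13.10	-14.00	-15.01	-9.45	-8.11	-10.03	-14.00	-13.48	-11.08	-8.11	-13.10	-11.85	-13.48	-9.45	-18.66
stacking_energy	-5.37	-10.51	-6.78	-6.57	-6.57	-8.26	-9.69	-6.78	-9.81	-14.59	-8.26	-10.51	-3.82	-9.81	-6.57	-5.37
duplex_free_energy	-1.00	-1.44	-1.28	-0.88	-1.45	-1.84	-2.17	-1.28	-1.30	-2.24	-1.84	-1.44	-0.58	-1.30	-1.45	-1.00
duplex_enthalpy	-7.9	-8.4	-7.8	-7.2	-8.5	-8.0	-10.6	-7.8	-8.2	-9.8	-8.0	-8.4	-7.2	-8.2	-8.5	-7.9
duplex_entropy	-22.2	-22.4	-21.0	-20.4	-22.7	-19.9	-27.2	-21.0	-22.2	-24.4	-19.9	-22.4	-21.3	-22.2	-22.7	-22.2
melting_temperature	54.50	97.73	58.42	57.02	54.71	85.97	72.55	58.42	86.44	136.12	85.97	97.73	36.73	86.44	54.71	54.50
bendability	-0.274	-0.205	-0.081	-0.280	0.017	-0.012	-0.033	-0.081	-0.110	-0.077	-0.012	-0.205	0.182	-0.110	0.017	-0.274
bending_stiffness	35	60	60	20	60	130	85	60	60	85	130	60	20	60	60	35
protein_deformability	2.9	2.3	2.1	1.6	9.8	6.1	12.1	2.1	4.5	4.0	6.1	2.3	6.3	4.5	9.8	2.9
minor_groove_width	2.85	3.75	3.60	3.40	3.85	3.95	4.30	3.60	3.70	4.10	3.95	3.75	4.20	3.70	3.85	2.85
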