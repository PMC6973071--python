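# Karplus parameter set "default" for 2'-fluoro-ribo sugars
#
# J(theta) = A*cos^2(theta) + B*cos(theta) + C   [Hz]
# theta    = a*nu_k + b                          [deg]
#
# Provenance:
#  * H-F coefficients transcribed from the generalized 1H-19F Karplus
#    relation for H-C-C-F fragments of 2'-fluorinated nucleosides
#    (Thibaudeau, Plavec & Chattopadhyaya, J. Org. Chem. 1998, 63,
#    4967-4984).  Transcribed from secondary sources; re-verify against
#    the original before quantitative use.
#  * H-H coefficients: simplified sugar-proton Karplus curve
#    (A = 10.2, B = -0.8, C = 0; Altona-school default) -- adequate for
#    qualitative N/S discrimination only.
#  * theta(nu) offsets fitted (max residual < 0.8 deg) on idealized
#    beta-D-2'F-ribofuranose geometry generated by the package's own
#    ring builder over P = 0..350, tau_m = 30..40.  The H1'-H2' offset
#    (+121.4 deg) reproduces the classic ribonucleoside value.
#
# path  A  B  C  nu_index  a  b
H1'-H2'	10.20	-0.80	0.00	1	1.0	121.4
H2'-H3'	10.20	-0.80	0.00	2	1.0	0.0
H3'-H4'	10.20	-0.80	0.00	3	1.0	-121.5
F2'-H1'	40.61	-4.22	5.88	1	1.0	-0.5
F2'-H3'	40.61	-4.22	5.88	2	1.0	121.9
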