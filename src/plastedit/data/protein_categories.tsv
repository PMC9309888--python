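protein	category
psaA	photosynthetic
psaB	photosynthetic
psaC	photosynthetic
psaI	photosynthetic
psaJ	photosynthetic
psaM	photosynthetic
psbA	photosynthetic
psbB	photosynthetic
psbC	photosynthetic
psbD	photosynthetic
psbE	photosynthetic
psbF	photosynthetic
psbH	photosynthetic
psbI	photosynthetic
psbJ	photosynthetic
psbK	photosynthetic
psbL	photosynthetic
psbM	photosynthetic
psbN	photosynthetic
psbT	photosynthetic
petA	photosynthetic
petB	photosynthetic
petD	photosynthetic
petG	photosynthetic
petL	photosynthetic
atpA	photosynthetic
atpB	photosynthetic
atpE	photosynthetic
atpH	photosynthetic
atpI	photosynthetic
rps2	non_photosynthetic
rps3	non_photosynthetic
rps4	non_photosynthetic
rps7	non_photosynthetic
rps8	non_photosynthetic
rps9	non_photosynthetic
rps11	non_photosynthetic
rps12	non_photosynthetic
rps14	non_photosynthetic
rps18	non_photosynthetic
rps19	non_photosynthetic
rpl2	non_photosynthetic
rpl5	non_photosynthetic
rpl14	non_photosynthetic
rpl16	non_photosynthetic
rpl20	non_photosynthetic
rpl36	non_photosynthetic
tufA	non_photosynthetic
ycf3	non_photosynthetic
clpP	non_photosynthetic
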