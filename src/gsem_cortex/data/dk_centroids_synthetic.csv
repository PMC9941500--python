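region,hemisphere,x,y,z
bankssts,L,-0.448858,-0.387561,0.805185
caudalanteriorcingulate,L,-0.481548,-0.779133,0.401327
caudalmiddlefrontal,L,-0.038651,-0.634134,-0.772257
cuneus,L,-0.616676,-0.757079,-0.215738
entorhinal,L,-0.521068,-0.842605,0.13603
frontalpole,L,-0.708889,-0.349081,-0.612878
fusiform,L,-0.195982,-0.976158,0.093305
inferiorparietal,L,-0.088531,-0.916489,-0.390142
inferiortemporal,L,-0.642369,0.121384,-0.756722
insula,L,-0.667378,-0.695433,-0.266419
isthmuscingulate,L,-0.760491,0.613948,0.211474
lateraloccipital,L,-0.12533,0.958276,0.256902
lateralorbitofrontal,L,-0.558169,0.796179,-0.233552
lingual,L,-0.260309,0.579949,-0.771944
medialorbitofrontal,L,-0.847313,0.529584,0.040027
middletemporal,L,-0.64883,0.059584,0.758597
paracentral,L,-0.809546,-0.112313,-0.576213
parahippocampal,L,-0.767102,-0.632843,0.105186
parsopercularis,L,-0.872252,-0.123444,0.47322
parsorbitalis,L,-0.151911,0.13127,-0.979638
parstriangularis,L,-0.314724,-0.865888,0.388827
pericalcarine,L,-0.522627,-0.566349,-0.637267
postcentral,L,-0.931529,0.114883,-0.345044
posteriorcingulate,L,-0.133903,0.654946,0.743717
precentral,L,-0.554528,-0.763383,0.331278
precuneus,L,-0.931612,-0.206628,0.299004
rostralanteriorcingulate,L,-0.230714,-0.946301,-0.226463
rostralmiddlefrontal,L,-0.239269,0.725906,0.644833
superiorfrontal,L,-0.386054,-0.023244,-0.922183
superiorparietal,L,-0.042728,0.97887,0.19997
superiortemporal,L,-0.12625,0.975335,-0.181058
supramarginal,L,-0.645308,0.677049,0.353811
temporalpole,L,-0.402617,-0.899029,0.172183
transversetemporal,L,-0.962197,0.225177,0.153209
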