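class,MAF1951-1980,COS1995,COS2007,COS2018
Artificialized territories,2.0,4.5,5.2,5.3
Agriculture,46.8,44.3,43.6,44.5
Grasslands,0.0,0.7,1.1,0.8
Agroforestry areas,0.4,0.6,0.9,0.9
Forests,39.7,43.7,44.5,43.8
Shrublands,11.1,6.1,4.6,4.6
Sparsely vegetated areas,0.0,0.0,0.0,0.0
Water bodies,0.0,0.1,0.1,0.1
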