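class,MAF1951-1980,COS1995,COS2007,COS2018
Artificialized territories,1.0,2.9,3.5,3.4
Agriculture,13.7,10.5,7.0,6.8
Agriculture-Vineyards,3.6,0.1,0.1,0.1
Agriculture-Fruit orchards,15.0,44.8,48.5,49.0
Agriculture-Olive groves,4.8,1.1,1.3,1.3
Grasslands,0.0,0.1,0.3,0.2
Forests-Cork oak,0.1,0.0,0.0,0.0
Forests-Other oaks,0.7,6.8,6.6,6.3
Forests-Chestnut,21.5,4.5,4.8,4.6
Forests-Eucalyptus,2.1,0.2,0.2,0.2
Forests-Invasive species,0.0,0.0,2.9,2.9
Forests-Deciduous forests,0.4,5.5,1.8,1.8
Forests-Pine woods,30.8,19.5,20.2,19.8
Shrublands,6.3,4.0,2.8,3.6
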