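species,b_MPa,c,P12_MPa,P50_MPa,P88_MPa,Vcmax25,kmax,reference
E. blakelyi,5.03,3.36,-2.72,-4.51,-6.12,86.88,,Li et al. (2018)
E. camaldulensis,4.10,4.35,-2.56,-3.77,-4.15,111.74,,Franks et al. (1995)
E. crebra,5.52,3.08,-2.83,-4.90,-6.41,86.88,,Bourne et al. (2017)
E. dunnii,5.56,3.06,-2.84,-4.93,-8.44,86.88,,Bourne et al. (2017)
E. globulus,2.55,8.30,-1.99,-2.44,-7.48,85.55,,Barotto et al. (2016)
E. grandis,3.58,5.29,-2.43,-3.34,-4.94,93.71,,Li et al. (2018); Bourne et al. (2017)
E. largiflorens,8.28,3.25,-4.40,-7.40,-9.95,86.88,,Li et al. (2018)
E. macrorhyncha,4.40,3.95,-2.61,-4.01,-5.95,86.88,,Li et al. (2018)
E. melliodora,5.67,3.02,-2.87,-5.02,-6.65,86.88,,Li et al. (2018)
E. obliqua,2.73,7.67,-2.08,-2.60,-3.64,86.88,,Pritzkow et al. (2020)
E. populnea,6.41,2.86,-3.12,-5.64,-7.70,86.88,,Li et al. (2018)
E. saligna,3.65,5.14,-2.45,-3.40,-5.16,76.67,,Bourne et al. (2017)
E. sideroxylon,4.54,3.79,-2.64,-4.12,-5.30,100.37,,Li et al. (2018)
E. tereticornis,4.36,3.99,-2.61,-3.98,-5.70,86.88,,Bourne et al. (2017)
E. viminalis,3.36,5.80,-2.35,-3.15,-4.43,77.60,,Li et al. (2018)
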