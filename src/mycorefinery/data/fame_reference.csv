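# schema_version: 1
# Reference fuel constants for pure fatty acid methyl esters.
# molecular_weight: formula weight of the methyl ester (g/mol);
# density_15c: kg/m3 at 15 degC; viscosity_40c: mm2/s at 40 degC; cetane: dimensionless.
# provenance "measured" rows are compiled from published experimental determinations of
# pure-ester fuel properties; "correlation" rows are filled from published MW/unsaturation
# regressions (no experimental fuel data exists for short-chain unsaturated esters);
# "interpolated" rows sit between measured homologs on the chain-length trend.
shorthand,carbons,double_bonds,molecular_weight,density_15c,viscosity_40c,cetane,provenance
C7:1,7,1,142.198,892.6,0.74,15.1,correlation
C8:0,8,0,158.241,881.0,1.20,33.6,measured
C9:1,9,1,170.252,886.9,1.15,23.6,correlation
C10:0,10,0,186.295,876.0,1.71,47.9,measured
C10:1,10,1,184.279,884.7,1.40,27.9,correlation
C12:0,12,0,214.349,873.0,2.43,66.7,measured
C14:0,14,0,242.403,870.0,3.30,66.2,measured
C15:0,15,0,256.430,868.5,3.83,75.0,interpolated
C16:0,16,0,270.457,867.0,4.38,85.9,measured
C16:1,16,1,268.441,876.4,3.67,51.0,measured
C17:0,17,0,284.484,865.5,5.10,93.0,interpolated
C18:0,18,0,298.511,864.0,5.85,101.0,measured
C18:1,18,1,296.495,873.9,4.51,59.3,measured
C18:2,18,2,294.479,888.5,3.65,38.2,measured
C18:3,18,3,292.463,900.5,3.14,22.7,measured
C20:0,20,0,326.565,861.5,7.00,100.0,interpolated
C20:1,20,1,324.549,870.0,5.77,73.2,measured
C22:0,22,0,354.619,858.8,8.10,103.0,interpolated
C22:1,22,1,352.603,868.0,7.33,74.2,measured
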