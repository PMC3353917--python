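variable,class,mean,sd
Net charge,natural,0.7100,5.335634
Net charge,random,0.0591,3.753989
Volume,natural,8706.4310,1067.166
Volume,random,9279.6090,356.8877
Surface,natural,3952.0580,603.5493
Surface,random,3951.5030,237.2047
Coil,natural,18.0276,9.03813
Coil,random,17.7349,6.887919
Beta,natural,14.7192,12.33831
Beta,random,7.4567,4.236918
Alpha,natural,23.3032,17.71133
Alpha,random,34.5538,7.646621
% Alpha,natural,33.8530,25.9784
% Alpha,random,49.3625,10.92395
% Beta,natural,21.3976,17.86945
% Beta,random,10.6532,6.052317
% Coil,natural,26.0394,12.77989
% Coil,random,25.3356,9.839893
% Secondary structure,natural,55.2100,17.92994
% Secondary structure,random,60.0151,10.10049
Surface hydrophobicity,natural,0.3568,0.0695038
Surface hydrophobicity,random,0.3738,0.05349438
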