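Frame,Contour ID,Pos.,X,Y,Length,Contrast,Asymmetry,Line width,Angle of normal,Class
1,0,0,12.437,30.191,41.02,155.2,0.031,3.12,120.0,bright
1,0,1,13.401,30.774,41.02,154.8,0.030,3.10,120.1,bright
1,0,2,14.375,31.342,41.02,155.0,0.032,3.14,120.0,bright
1,1,0,80.210,15.006,12.55,98.7,0.110,2.84,45.2,bright
1,1,1,79.488,15.731,12.55,98.1,0.108,2.80,45.0,bright
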