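phantom,region,method,dose_gy
Cylindrical,Phantom,OLINDA1.1,3.3
Cylindrical,Phantom,VoxelMed,2.8
Cylindrical,Phantom,RAYDOSE,3.0
Geometrical,To17a,OLINDA1.1,6.3
Geometrical,To17a,VoxelMed,3.0
Geometrical,To17a,RAYDOSE,4.0
Geometrical,To17b,OLINDA1.1,0.8
Geometrical,To17b,VoxelMed,0.4
Geometrical,To17b,RAYDOSE,0.5
Geometrical,To26,OLINDA1.1,15.4
Geometrical,To26,VoxelMed,9.0
Geometrical,To26,RAYDOSE,10.7
Geometrical,E20,OLINDA1.1,21.1
Geometrical,E20,VoxelMed,16.1
Geometrical,E20,RAYDOSE,17.6
Geometrical,E30,OLINDA1.1,23.0
Geometrical,E30,VoxelMed,20.7
Geometrical,E30,RAYDOSE,20.9
Geometrical,E38,OLINDA1.1,24.1
Geometrical,E38,VoxelMed,23.9
Geometrical,E38,RAYDOSE,23.7
Geometrical,P38,OLINDA1.1,2.5
Geometrical,P38,VoxelMed,2.0
Geometrical,P38,RAYDOSE,2.1
Geometrical,P39a,OLINDA1.1,2.5
Geometrical,P39a,VoxelMed,2.0
Geometrical,P39a,RAYDOSE,2.1
Geometrical,P39b,OLINDA1.1,2.1
Geometrical,P39b,VoxelMed,2.0
Geometrical,P39b,RAYDOSE,2.0
Geometrical,Tu38a,OLINDA1.1,2.5
Geometrical,Tu38a,VoxelMed,2.0
Geometrical,Tu38a,RAYDOSE,1.9
Geometrical,Tu38b,OLINDA1.1,2.4
Geometrical,Tu38b,VoxelMed,2.0
Geometrical,Tu38b,RAYDOSE,2.0
Anthropomorphic,Lesion,OLINDA1.1,102.3
Anthropomorphic,Lesion,VoxelMed,91.3
Anthropomorphic,Lesion,RAYDOSE,97.9
Anthropomorphic,Pancreas,OLINDA1.1,13.6
Anthropomorphic,Pancreas,VoxelMed,11.9
Anthropomorphic,Pancreas,RAYDOSE,12.2
Anthropomorphic,Kidneys,OLINDA1.1,12.9
Anthropomorphic,Kidneys,VoxelMed,11.4
Anthropomorphic,Kidneys,RAYDOSE,11.8
Anthropomorphic,Spleen,OLINDA1.1,22.0
Anthropomorphic,Spleen,VoxelMed,19.6
Anthropomorphic,Spleen,RAYDOSE,20.3
Anthropomorphic,Liver,OLINDA1.1,10.4
Anthropomorphic,Liver,VoxelMed,9.3
Anthropomorphic,Liver,RAYDOSE,9.8
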