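/root/pkg/src/bulkfhir__init__.pyhttp_surface.pyconformance_suite.pyclient.pysynthetic_population.pyfhir_core.pybackend_auth.pyrsa_jws.pyexport_engine.py       �   ����=�{�X\���I���         �   ��������8<d��I���         �   ������EZ���I���         �   d���gFN��&��I���         �   -������i��I���         �   ���:+��E��I���         cli.py����E�O���I���         �   �����8l��
���I���         �   ����=�{�X\���I���         �   V����n�t����I���                                         �7{i:;Eo{y�7{i:;Eo{y��������� �   ��������
      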