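/root/pkg/teststest_http_surface.pytest_client.pytest_fhir_core.pytest_synthetic_population.pyconftest.pytest_conformance.pytest_export_engine.pytest_acceptance.pyselection_oracle.pytest_backend_auth.py      �   �����꺉����I���         �   ����$�N�ܬ���I���         �   ����v�D�1�I���         �   L�����Z�����I���         �   ���@�6*���I���         �   �����	)Tэ
�I���         �   �����P�����e�I���         �   �����sf�[���I���         �   S����s�2re��I���         �   ���p6���s��I���                                         �) /FS(IyX3�) /FS(IyX3��������� �   ��������
      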